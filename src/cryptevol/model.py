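"""Six-type colonic crypt model: genotype graph, parameters, and conversion rates.

The colon is modelled as a population of crypts. Each crypt is homogeneous with
respect to two driver events — inactivation of the APC tumour suppressor (two
hits) and activation of the KRAS oncogene (one hit) — giving six crypt types:

    1: APC+/+ KRAS-     2: APC+/- KRAS-     3: APC-/- KRAS-
    4: APC+/+ KRAS+     5: APC+/- KRAS+     6: APC-/- KRAS+

Type 6 is the advanced-adenoma type. Crypts change type by *conversion*: a
mutant stem cell arises in one of the crypt's ``n_sc`` stem cells and fixates
via a Moran birth-death process. The per-crypt, per-year conversion rate on
graph edge (i, j) is

    R_ij = n_sc * r1 * F_i * u_ij * rho(F_j / F_i, n_sc)

where ``n_sc * r1 * F_i`` is the number of stem-cell divisions per crypt per
year in a type-i crypt, ``u_ij`` the per-division mutation rate of the edge
(APC hit ``u`` or KRAS activation ``mu``), and ``rho`` the Moran fixation
probability of a single mutant with relative fitness ``F_j / F_i``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "EDGES",
    "APC_EDGES",
    "KRAS_EDGES",
    "APC_FIRST_HIT_EDGES",
    "GENOTYPE_LABELS",
    "CryptType",
    "ModelParams",
    "ConversionMatrix",
    "fixation_probability",
    "conversion_matrix",
    "DomainError",
]


class DomainError(ValueError):
    """An argument lies outside the model's domain."""


#: The seven edges of the mutation graph, ordered (used everywhere, incl. SSA).
EDGES: tuple[tuple[int, int], ...] = (
    (1, 2), (2, 3), (1, 4), (2, 5), (4, 5), (3, 6), (5, 6),
)

#: Edges corresponding to an APC hit (rate u).
APC_EDGES = frozenset({(1, 2), (2, 3), (4, 5), (5, 6)})

#: Edges corresponding to KRAS activation (rate mu).
KRAS_EDGES = frozenset({(1, 4), (2, 5), (3, 6)})

#: APC edges hitting the first of two intact alleles (optional multiplicity 2).
APC_FIRST_HIT_EDGES = frozenset({(1, 2), (4, 5)})

GENOTYPE_LABELS = {
    1: "APC+/+ KRAS-",
    2: "APC+/- KRAS-",
    3: "APC-/- KRAS-",
    4: "APC+/+ KRAS+",
    5: "APC+/- KRAS+",
    6: "APC-/- KRAS+",
}


@dataclass(frozen=True)
class CryptType:
    """One of the six crypt genotypes."""

    id: int
    genotype_label: str = ""

    def __post_init__(self) -> None:
        if self.id not in GENOTYPE_LABELS:
            raise DomainError(f"crypt type id must be 1..6, got {self.id}")
        expected = GENOTYPE_LABELS[self.id]
        if self.genotype_label == "":
            object.__setattr__(self, "genotype_label", expected)
        elif self.genotype_label != expected:
            raise DomainError(
                f"type {self.id} is {expected!r}, not {self.genotype_label!r}"
            )

    @property
    def apc_hits(self) -> int:
        return (self.id - 1) % 3 if self.id <= 3 else (self.id - 4) % 3

    @property
    def kras_mutant(self) -> bool:
        return self.id >= 4

    @property
    def is_advanced_adenoma(self) -> bool:
        """Type 6 is absorbing with respect to conversions."""
        return self.id == 6


def fixation_probability(relative_fitness: float, n_sc: int) -> float:
    """Moran fixation probability of a single mutant stem cell.

    rho(r, n) = (1 - 1/r) / (1 - 1/r**n) for r != 1, and 1/n for r = 1,
    in a constant population of ``n_sc`` stem cells.

    Parameters
    ----------
    relative_fitness:
        Fitness of the invading type relative to the resident, r > 0.
    n_sc:
        Number of stem cells per crypt, >= 1.
    """
    r = float(relative_fitness)
    if not math.isfinite(r) or r <= 0:
        raise DomainError(f"relative fitness must be positive, got {relative_fitness}")
    n = int(n_sc)
    if n < 1 or n != n_sc:
        raise DomainError(f"n_sc must be an integer >= 1, got {n_sc}")
    if n == 1:
        return 1.0
    if abs(r - 1.0) < 1e-12:
        return 1.0 / n
    a = 1.0 / r
    # For deleterious invaders in large populations a**n overflows; switch to
    # the log form rho = (a - 1) / (a**n - 1) ~ (a - 1) * a**(-n).
    if a > 1.0 and n * math.log(a) > 700.0:
        return math.exp(math.log(a - 1.0) - n * math.log(a))
    return (1.0 - a) / (1.0 - a**n)


_FITNESS_DEFAULT = (1.0, 1.4, 2.2, 1.6, 2.0, 3.0)
_GAMMA_DEFAULT = (0.5, 0.35, 0.35, 1.01)  # gamma_3, gamma_4, gamma_5, gamma_6


@dataclass(frozen=True)
class ModelParams:
    """All kinetic and structural constants of the crypt model.

    Rates are per year; mutation rates are per stem-cell division. ``fitness``
    holds the relative stem-cell fitnesses F_1..F_6 (F_1 = 1); ``gamma`` holds
    the crypt fission rates of types 3..6 (types 1-2 do not undergo fission).
    ``K_A`` caps the fission of type-3 (APC-/- KRAS-) crypts, ``K_R`` that of
    types 4-5 (KRAS+), through a shared logistic competition term in
    n_3 + n_4 + n_5. Detection of an advanced adenoma corresponds to a colony
    of ``detection_size`` type-6 crypts.

    Defaults for u, mu, delta, delta6, gamma_6 and detection_size are the
    published point values; fitness, fission rates of types 3-5, n_sc, r1,
    n_crypt and the carrying capacities are configuration-level choices (see
    docs/methods.md) and are routinely overridden or fitted.
    """

    u: float = 1e-7
    mu: float = 1e-9
    n_sc: int = 5
    r1: float = 150.0
    fitness: tuple[float, ...] = _FITNESS_DEFAULT
    gamma: tuple[float, ...] = _GAMMA_DEFAULT
    delta: float = 0.05
    delta6: float = 0.05
    K_A: float = 5000.0
    K_R: float = 2500.0
    n_crypt: float = 1e7
    detection_size: int = 100
    apc_first_hit_multiplicity: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fitness", tuple(float(f) for f in self.fitness))
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        if len(self.fitness) != 6:
            raise DomainError("fitness must have six entries F_1..F_6")
        if len(self.gamma) != 4:
            raise DomainError("gamma must have four entries (types 3..6)")
        if not (0.0 < self.u < 1.0) and self.u != 0.0:
            raise DomainError(f"u must be in [0, 1), got {self.u}")
        if not (0.0 < self.mu < 1.0) and self.mu != 0.0:
            raise DomainError(f"mu must be in [0, 1), got {self.mu}")
        if self.n_sc < 1:
            raise DomainError("n_sc must be >= 1")
        if any(f <= 0 for f in self.fitness):
            raise DomainError("fitness values must be positive")
        if any(g < 0 for g in self.gamma):
            raise DomainError("fission rates must be non-negative")
        if self.delta < 0 or self.delta6 < 0 or self.r1 < 0:
            raise DomainError("rates must be non-negative")
        if not (self.K_A > 0 and self.K_R > 0):
            raise DomainError("carrying capacities must be positive")
        if self.n_crypt < 0:
            raise DomainError("n_crypt must be non-negative")
        if self.detection_size < 1:
            raise DomainError("detection_size must be >= 1")
        if self.apc_first_hit_multiplicity <= 0:
            raise DomainError("apc_first_hit_multiplicity must be positive")

    # Convenience accessors (gamma indexed by crypt type).
    @property
    def gamma3(self) -> float:
        return self.gamma[0]

    @property
    def gamma4(self) -> float:
        return self.gamma[1]

    @property
    def gamma5(self) -> float:
        return self.gamma[2]

    @property
    def gamma6(self) -> float:
        return self.gamma[3]

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "ModelParams":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class ConversionMatrix:
    """Per-crypt, per-year conversion rates R_ij on the six-type graph.

    Only the seven edges of the mutation graph are present.
    """

    rates: tuple[float, ...]  # aligned with EDGES

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != len(EDGES):
            raise DomainError(f"need {len(EDGES)} edge rates, got {len(self.rates)}")
        if any(r < 0 or not math.isfinite(r) for r in self.rates):
            raise DomainError("conversion rates must be finite and non-negative")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ConversionMatrix":
        extra = set(mapping) - set(EDGES)
        if extra:
            raise DomainError(f"edges outside the mutation graph: {sorted(extra)}")
        return cls(tuple(float(mapping.get(e, 0.0)) for e in EDGES))

    def __getitem__(self, edge: tuple[int, int]) -> float:
        try:
            return self.rates[EDGES.index(edge)]
        except ValueError:
            raise KeyError(f"{edge} is not an edge of the mutation graph") from None

    def as_dict(self) -> dict:
        return dict(zip(EDGES, self.rates))

    def with_rates(self, **edge_updates) -> "ConversionMatrix":
        """Return a copy with named edges replaced, e.g. R36=0.0."""
        d = self.as_dict()
        for key, val in edge_updates.items():
            if not (key.startswith("R") and len(key) == 3):
                raise DomainError(f"bad edge key {key!r}; use e.g. R36")
            edge = (int(key[1]), int(key[2]))
            if edge not in d:
                raise DomainError(f"{edge} is not an edge of the mutation graph")
            d[edge] = float(val)
        return ConversionMatrix.from_mapping(d)


def conversion_matrix(params: ModelParams) -> ConversionMatrix:
    """Crypt conversion rates from the mutation-selection layer.

    R_ij = n_sc * r1 * F_i * u_ij * rho(F_j/F_i, n_sc), where u_ij is the APC
    hit rate ``u`` (times ``apc_first_hit_multiplicity`` on the two first-hit
    edges) or the KRAS activation rate ``mu``.
    """
    F = params.fitness
    rates = []
    for edge in EDGES:
        i, j = edge
        if edge in APC_EDGES:
            u_ij = params.u
            if edge in APC_FIRST_HIT_EDGES:
                u_ij *= params.apc_first_hit_multiplicity
        else:
            u_ij = params.mu
        rho = fixation_probability(F[j - 1] / F[i - 1], params.n_sc)
        rates.append(params.n_sc * params.r1 * F[i - 1] * u_ij * rho)
    return ConversionMatrix(tuple(rates))
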