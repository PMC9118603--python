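"""Fixed-effects design and the catalogue of random-effect components.

The area-level model for the sqrt-scale direct estimates is

    y = X beta + sum_i Z^(i) v^(i) + e,      e ~ N(0, Sigma),

with Sigma a known diagonal matrix of smoothed sampling variances.  Each
random-effect component couples a *varying* factor V (d levels, unknown
covariance V, here scalar or diagonal) with a *grouping* factor A
(l levels, known precision Q_A): the effect vector has length q = d*l,
ordered V-level-within-A-level, and prior precision Q_A (x) V^{-1}
(Kronecker product).  Q_A is the identity for exchangeable components
and the intrinsic-CAR precision for the spatial component.

The component catalogue:

================ ========== ========== =========================== ======
name             factor V   structure  factor A                    q
================ ========== ========== =========================== ======
RES_DIST         residence  diagonal   district                    2*L
RES_DIST_AGE     residence  diagonal   district x age              2*L*A
RES_DIST_SEX     residence  diagonal   district x sex              2*L*2
AGE_DIST         age        diagonal   district                    A*L
SP_DIST          1          scalar     district (ICAR)             L
WN_DIV           1          scalar     division x res x age x sex  .
WN_DIST          1          scalar     district x res x age x sex  D
================ ========== ========== =========================== ======

(L districts, A age groups.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import AdjacencyGraph, DomainLattice, car_precision

__all__ = [
    "COMPONENT_NAMES",
    "DEFAULT_COMPONENT_SETS",
    "FixedDesign",
    "RandomEffectComponent",
    "ModelSpec",
    "fixed_design",
    "build_component",
    "assemble_model",
]

COMPONENT_NAMES = (
    "RES_DIST",
    "RES_DIST_AGE",
    "RES_DIST_SEX",
    "AGE_DIST",
    "SP_DIST",
    "WN_DIV",
    "WN_DIST",
)

#: Final per-indicator component selections: the residence-by-district
#: intercepts are dropped for stunting and the spatial component for
#: wasting (their variance parameters were not significant); the
#: underweight model keeps the full catalogue.
DEFAULT_COMPONENT_SETS = {
    "stunting": (
        "RES_DIST_AGE",
        "RES_DIST_SEX",
        "AGE_DIST",
        "SP_DIST",
        "WN_DIV",
        "WN_DIST",
    ),
    "wasting": (
        "RES_DIST",
        "RES_DIST_AGE",
        "RES_DIST_SEX",
        "AGE_DIST",
        "WN_DIV",
        "WN_DIST",
    ),
    "underweight": COMPONENT_NAMES,
}


@dataclass(frozen=True)
class FixedDesign:
    """Treatment-coded D x p design: intercept, age contrasts vs the
    youngest group, division contrasts vs the first division, urban vs
    rural, male vs female."""

    X: np.ndarray
    labels: tuple[str, ...]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def fixed_design(lattice: DomainLattice) -> FixedDesign:
    """Build the fixed-effects design matrix for a lattice.

    p = 1 + (n_ages - 1) + (n_divisions - 1) + 1 + 1 columns; reference
    levels are the first level of each factor (rural, female, youngest
    age, first division).
    """
    frame = lattice.frame
    cols: list[np.ndarray] = [np.ones(len(frame))]
    labels: list[str] = ["intercept"]
    for level in lattice.level_sets["age_group"][1:]:
        cols.append((frame["age_group"] == level).to_numpy(float))
        labels.append(f"age_group[{level}]")
    for level in lattice.divisions[1:]:
        cols.append((frame["division"] == level).to_numpy(float))
        labels.append(f"division[{level}]")
    for level in lattice.level_sets["residence"][1:]:
        cols.append((frame["residence"] == level).to_numpy(float))
        labels.append(f"residence[{level}]")
    for level in lattice.level_sets["sex"][1:]:
        cols.append((frame["sex"] == level).to_numpy(float))
        labels.append(f"sex[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    return FixedDesign(X=X, labels=tuple(labels))


@dataclass
class RandomEffectComponent:
    """One term Z v of the linear predictor.

    ``effect_index`` encodes the incidence matrix Z (one 1 per row):
    domain j loads on effect column ``effect_index[j] = a_j * d + k_j``
    where ``a_j`` is the A-level and ``k_j`` the V-level of the domain
    (V-within-A ordering).  ``Q_A is None`` means the identity.
    """

    name: str
    effect_index: np.ndarray
    d: int
    l: int
    v_levels: tuple[str, ...]
    Q_A: np.ndarray | None = None
    variance_structure: str = "diagonal"
    prior_shape: float = 0.001
    prior_rate: float = 0.001

    @property
    def q(self) -> int:
        return self.d * self.l

    @property
    def n_parameters(self) -> int:
        return 1 if self.variance_structure == "scalar" else self.d

    @property
    def is_icar(self) -> bool:
        return self.Q_A is not None

    @property
    def v_index_of_effect(self) -> np.ndarray:
        """V-level of each effect column (length q)."""
        return np.tile(np.arange(self.d), self.l)

    def project(self, v: np.ndarray) -> np.ndarray:
        """Z v: map an effect vector to the domain scale."""
        return np.asarray(v)[self.effect_index]

    def crossprod(self, x: np.ndarray) -> np.ndarray:
        """Z' x for a domain-scale vector x."""
        return np.bincount(self.effect_index, weights=x, minlength=self.q)

    def variances_per_effect(self, variances: np.ndarray) -> np.ndarray:
        variances = np.broadcast_to(np.atleast_1d(variances), (self.d,))
        return np.tile(variances, self.l)

    def prior_precision(self, variances: np.ndarray) -> np.ndarray:
        """Dense q x q prior precision Q_A (x) V^{-1} (oracle path)."""
        variances = np.broadcast_to(np.atleast_1d(np.asarray(variances, float)), (self.d,))
        qa = self.Q_A if self.Q_A is not None else np.eye(self.l)
        return np.kron(qa, np.diag(1.0 / variances))


def _interaction_codes(lattice: DomainLattice, factors: tuple[str, ...]) -> tuple[np.ndarray, int]:
    """Row-major level codes for an interaction of lattice factors."""
    code = np.zeros(lattice.n_domains, dtype=np.int64)
    size = 1
    for f in factors:
        levels = lattice.divisions if f == "division" else lattice.level_sets[f]
        code = code * len(levels) + lattice.codes(f)
        size *= len(levels)
    return code, size


_CATALOGUE: dict[str, dict] = {
    "RES_DIST": {"v": "residence", "a": ("district",)},
    "RES_DIST_AGE": {"v": "residence", "a": ("district", "age_group")},
    "RES_DIST_SEX": {"v": "residence", "a": ("district", "sex")},
    "AGE_DIST": {"v": "age_group", "a": ("district",)},
    "SP_DIST": {"v": None, "a": ("district",), "spatial": True},
    "WN_DIV": {"v": None, "a": ("division", "residence", "age_group", "sex")},
    "WN_DIST": {"v": None, "a": ("district", "residence", "age_group", "sex")},
}


def build_component(
    name: str,
    lattice: DomainLattice,
    graph: AdjacencyGraph | None = None,
    prior_shape: float = 0.001,
    prior_rate: float = 0.001,
) -> RandomEffectComponent:
    """Instantiate one catalogued component on a lattice.

    The spatial component requires ``graph`` and carries the ICAR
    precision over districts (in lattice district order); every other
    component has identity Q_A.
    """
    if name not in _CATALOGUE:
        raise ValueError(f"unknown component {name!r}; choose from {COMPONENT_NAMES}")
    spec = _CATALOGUE[name]
    a_code, l = _interaction_codes(lattice, spec["a"])
    if spec["v"] is None:
        d, v_code, v_levels = 1, np.zeros(lattice.n_domains, np.int64), ("1",)
        structure = "scalar"
    else:
        v_levels = tuple(lattice.level_sets[spec["v"]])
        d = len(v_levels)
        v_code = lattice.codes(spec["v"])
        structure = "diagonal"
    qa = None
    if spec.get("spatial"):
        if graph is None:
            raise ValueError("SP_DIST requires an adjacency graph")
        graph.validate_against(lattice)
        qa = car_precision(graph, order=lattice.districts)
    return RandomEffectComponent(
        name=name,
        effect_index=a_code * d + v_code,
        d=d,
        l=l,
        v_levels=v_levels,
        Q_A=qa,
        variance_structure=structure,
        prior_shape=prior_shape,
        prior_rate=prior_rate,
    )


@dataclass
class ModelSpec:
    """Assembled area-level model: response, design, components, and the
    fixed diagonal sampling covariance."""

    y: np.ndarray
    design: FixedDesign
    components: list[RandomEffectComponent]
    sigma2_e: np.ndarray
    lattice: DomainLattice | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        D = len(self.y)
        if self.design.X.shape[0] != D:
            raise ValueError("design matrix row count does not match response")
        self.sigma2_e = np.asarray(self.sigma2_e, float)
        if self.sigma2_e.shape != (D,):
            raise ValueError("sigma2_e must be a length-D diagonal")
        if np.any(self.sigma2_e <= 0):
            raise ValueError("sampling variances must be strictly positive")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        for comp in self.components:
            if len(comp.effect_index) != D:
                raise ValueError(f"component {comp.name}: incidence length mismatch")
            if comp.effect_index.max(initial=-1) >= comp.q:
                raise ValueError(f"component {comp.name}: effect index out of range")

    @property
    def n_domains(self) -> int:
        return len(self.y)

    def eta(self, beta: np.ndarray, effects: dict[str, np.ndarray]) -> np.ndarray:
        """Linear predictor X beta + sum_i Z^(i) v^(i)."""
        out = self.design.X @ np.asarray(beta, float)
        for comp in self.components:
            out = out + comp.project(effects[comp.name])
        return out

    def summary(self) -> str:
        lines = [
            f"area-level model: D={self.n_domains}, p={self.design.p} fixed effects",
            "components:",
        ]
        for c in self.components:
            kind = "ICAR" if c.is_icar else "iid"
            lines.append(
                f"  {c.name:13s} {c.variance_structure:8s} d={c.d} l={c.l} "
                f"q={c.q} params={c.n_parameters} Q_A={kind}"
            )
        return "\n".join(lines)


def assemble_model(
    response: np.ndarray,
    components: list[RandomEffectComponent],
    design: FixedDesign,
    sigma2_e: np.ndarray,
    lattice: DomainLattice | None = None,
) -> ModelSpec:
    """Validate dimensions and return the full :class:`ModelSpec`."""
    return ModelSpec(
        y=np.asarray(response, float),
        design=design,
        components=list(components),
        sigma2_e=np.asarray(sigma2_e, float),
        lattice=lattice,
    )
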