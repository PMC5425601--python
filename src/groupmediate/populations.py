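"""Population specifications for the two-group mediation simulation study.

The catalog crosses three structural settings with seven residual-variance
patterns, giving 21 named populations:

* structural set I — a = 0.424, b = 0.390 in both groups (equal, non-zero
  indirect effects: a*b = 0.165 in each group, difference 0);
* structural set II — a = 0 in G1 and a = 0.141 in G2, b = 0.390 in both
  (indirect effects 0 and 0.055, difference -0.055);
* structural set III — a = 0 in G1 and a = 0.424 in G2 (indirect effects 0
  and 0.165, difference -0.165).

Variance patterns: "0" is the homogeneous baseline (all residual variances
1); "M1"-"M3" shrink the mediator residual variance in G1 to 0.5 while G2's
is 1.0, 1.5 or 2.0; "Y1"-"Y3" do the same to the outcome residual variance.
The direct effect c' is zero everywhere and X ~ N(0, 1) in both groups — the
unit X variance is the value consistent with the catalog's explained-variance
bookkeeping (0.424^2/(0.424^2+1) = 0.152).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MediationDataset

__all__ = [
    "GroupParams",
    "PopulationSpec",
    "population_catalog",
    "explained_variance",
    "population_indirect_effects",
    "generate_dataset",
]

G1, G2 = "G1", "G2"

_STRUCTURAL = {
    "I": ((0.424, 0.390), (0.424, 0.390)),
    "II": ((0.000, 0.390), (0.141, 0.390)),
    "III": ((0.000, 0.390), (0.424, 0.390)),
}
# (psi_M, psi_Y) per group
_VARIANCE = {
    "0": ((1.0, 1.0), (1.0, 1.0)),
    "M1": ((0.5, 1.0), (1.0, 1.0)),
    "M2": ((0.5, 1.0), (1.5, 1.0)),
    "M3": ((0.5, 1.0), (2.0, 1.0)),
    "Y1": ((1.0, 0.5), (1.0, 1.0)),
    "Y2": ((1.0, 0.5), (1.0, 1.5)),
    "Y3": ((1.0, 0.5), (1.0, 2.0)),
}


@dataclass(frozen=True)
class GroupParams:
    """Structural paths and residual variances of one group's equations."""

    a: float
    b: float
    cprime: float
    psi_m: float
    psi_y: float
    var_x: float = 1.0

    def __post_init__(self):
        if self.psi_m < 0 or self.psi_y < 0 or self.var_x <= 0:
            raise ValueError("variances must be non-negative (var_x positive)")


@dataclass(frozen=True)
class PopulationSpec:
    """A named two-group population: per-group paths and variances."""

    name: str
    groups: dict[str, GroupParams]

    def labels(self) -> tuple[str, str]:
        return tuple(self.groups)  # insertion order: (G1, G2)


def population_catalog() -> dict[str, PopulationSpec]:
    """All 21 named populations (structural sets I/II/III x variance
    patterns 0, M1-M3, Y1-Y3), c' = 0 everywhere, var(X) = 1."""
    catalog = {}
    for sname, sval in _STRUCTURAL.items():
        for vname, vval in _VARIANCE.items():
            name = f"{sname}-{vname}"
            groups = {}
            for lab, (ab, psis) in zip((G1, G2), zip(sval, vval)):
                a, b = ab
                psi_m, psi_y = psis
                groups[lab] = GroupParams(a=a, b=b, cprime=0.0, psi_m=psi_m, psi_y=psi_y)
            catalog[name] = PopulationSpec(name=name, groups=groups)
    return catalog


def explained_variance(pop: PopulationSpec) -> dict[str, tuple[float, float]]:
    """Population R-squared of the M- and Y-equations per group.

    R2_M = a^2 var_x / (a^2 var_x + psi_M). For Y, the explained part is
    b^2 var(M) + c'^2 var_x + 2 a b c' var_x with var(M) = a^2 var_x + psi_M.
    """
    out = {}
    for lab, g in pop.groups.items():
        var_m = g.a**2 * g.var_x + g.psi_m
        r2_m = (g.a**2 * g.var_x / var_m) if var_m > 0 else 0.0
        expl_y = g.b**2 * var_m + g.cprime**2 * g.var_x + 2 * g.a * g.b * g.cprime * g.var_x
        var_y = expl_y + g.psi_y
        r2_y = expl_y / var_y if var_y > 0 else 0.0
        out[lab] = (r2_m, r2_y)
    return out


def population_indirect_effects(pop: PopulationSpec) -> dict[str, float]:
    """True simple indirect effects per group and the G1-minus-G2 difference."""
    vals = {lab: g.a * g.b for lab, g in pop.groups.items()}
    l1, l2 = pop.labels()
    vals["difference"] = vals[l1] - vals[l2]
    return vals


def generate_dataset(
    pop: PopulationSpec, n_g1: int, n_g2: int, seed=None
) -> MediationDataset:
    """Draw a dataset from the population model.

    Per group: X ~ N(0, var_x), M = a X + e_M with e_M ~ N(0, psi_M),
    Y = b M + c' X + e_Y with e_Y ~ N(0, psi_Y); intercepts are zero.
    Deterministic given ``seed`` (an int, SeedSequence, or Generator).
    """
    if n_g1 < 1 or n_g2 < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    xs, ms, ys, gs = [], [], [], []
    for lab, n in zip(pop.labels(), (n_g1, n_g2)):
        g = pop.groups[lab]
        x = rng.normal(0.0, np.sqrt(g.var_x), n)
        m = g.a * x + rng.normal(0.0, np.sqrt(g.psi_m), n)
        y = g.b * m + g.cprime * x + rng.normal(0.0, np.sqrt(g.psi_y), n)
        xs.append(x)
        ms.append(m)
        ys.append(y)
        gs.append(np.full(n, lab, dtype=object))
    return MediationDataset(
        x=np.concatenate(xs),
        m=np.concatenate(ms),
        y=np.concatenate(ys),
        group=np.concatenate(gs),
    )
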