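"""Replication engine: Type I error, power, coverage, width, and miss-side
behaviour of the inference methods under the catalog populations.

A :class:`SimulationCondition` pairs a population with group sizes, a
replication count, a method list, and a master seed. :func:`run_condition`
generates a fresh dataset per replication (per-replication seeds derived from
the master seed through a counter scheme, so any replication is independently
reproducible), runs each requested method, and aggregates rejection rates,
coverage, interval widths, left/right-side miss counts, and per-parameter
bias, each rate carrying its Monte Carlo standard error
sqrt(p(1-p)/n_reps).

The single-group analysis codes the first catalog group as the reference
(dummy 0) and the second as focal, so its "difference" estimand is
G2-minus-G1; the multi-group difference is G1-minus-G2. Truth values for
coverage bookkeeping follow each parameterization's own convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GroupCoding
from .errors import SimulationError
from .inference import (
    DIFFERENCE,
    bc_ci,
    bootstrap_draw_sets,
    ci_excludes_zero,
    lr_test,
    monte_carlo_draws,
    percentile_ci,
    wald_diff_test,
    wald_product_test,
    z_test_a3,
)
from .model import fit_multi_group, fit_single_group, simple_indirect_effects
from .populations import (
    PopulationSpec,
    generate_dataset,
    population_catalog,
    population_indirect_effects,
)

__all__ = [
    "SimulationCondition",
    "SimulationSummary",
    "METHODS",
    "run_condition",
    "miss_side_tally",
    "replicate_tables",
    "SIZE_PATTERNS",
]

SIZE_PATTERNS = ((150, 150), (200, 100), (100, 200))

# tag -> (approach, kind); kind: "test" or interval family "PC"/"BC"/"MC"
METHODS = {
    "za3S": ("single", "test"),
    "WdiffS": ("single", "test"),
    "PCindS": ("single", "PC"),
    "BCindS": ("single", "BC"),
    "PCdiffS": ("single", "PC"),
    "BCdiffS": ("single", "BC"),
    "LRaM": ("multi", "test"),
    "LRdiffM": ("multi", "test"),
    "WdiffM": ("multi", "test"),
    "PCindM": ("multi", "PC"),
    "BCindM": ("multi", "BC"),
    "MCindM": ("multi", "MC"),
    "PCdiffM": ("multi", "PC"),
    "BCdiffM": ("multi", "BC"),
    "MCdiffM": ("multi", "MC"),
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    population: PopulationSpec
    n_g1: int
    n_g2: int
    n_reps: int = 1000
    methods: tuple[str, ...] = ("za3S", "LRaM")
    seed: int = 0
    B: int = 1000  # bootstrap draws per replication
    R: int = 1000  # Monte Carlo draws per replication
    level: float = 0.95
    ind_targets: tuple[str, ...] | None = None  # None -> both groups

    def __post_init__(self):
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class SimulationSummary:
    """Aggregated results of one condition.

    ``results`` has one row per (method, target) with columns: truth, n_used,
    reject_rate, mc_se, and for interval methods coverage, mean_width,
    left_miss, right_miss, left_right_ratio (NaN when there are no right
    misses, flagged via ratio_defined). ``bias`` has one row per tracked
    parameter with mean estimate, truth, bias, and relative bias.
    """

    population: str
    n_g1: int
    n_g2: int
    n_reps: int
    seed: int
    results: pd.DataFrame
    bias: pd.DataFrame
    n_failures: int = 0

    def rate(self, method: str, target: str | None = None) -> float:
        df = self.results
        sel = df[df["method"] == method]
        if target is not None:
            sel = sel[sel["target"] == target]
        if len(sel) != 1:
            raise KeyError(f"no unique row for method={method!r}, target={target!r}")
        return float(sel["reject_rate"].iloc[0])

    def row(self, method: str, target: str) -> pd.Series:
        df = self.results
        sel = df[(df["method"] == method) & (df["target"] == target)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for {method!r}/{target!r}")
        return sel.iloc[0]


def miss_side_tally(
    lowers: np.ndarray, uppers: np.ndarray, true_value: float
) -> tuple[int, int, int]:
    """(left, right, cover) counts for closed intervals against the truth.

    A left-side miss has the truth strictly below the interval
    (true < lower); a right-side miss has it strictly above (true > upper);
    boundary contact counts as covering. The three counts partition the
    intervals.
    """
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    left = int(np.sum(true_value < lowers))
    right = int(np.sum(true_value > uppers))
    cover = len(lowers) - left - right
    return left, right, cover


def _rep_seed(master: int, rep: int, stream: int) -> np.random.SeedSequence:
    # counter-based scheme: each (replication, stream) is independently
    # reproducible without sequential coupling
    return np.random.SeedSequence(entropy=(master, rep, stream))


def run_condition(condition: SimulationCondition) -> SimulationSummary:
    """Run all replications of one condition and aggregate the metrics."""
    cond = condition
    pop = cond.population
    l1, l2 = pop.labels()
    truths = population_indirect_effects(pop)
    coding = GroupCoding(reference=l1, focal=l2)

    single_tags = [m for m in cond.methods if METHODS[m][0] == "single"]
    multi_tags = [m for m in cond.methods if METHODS[m][0] == "multi"]
    sboot_tags = [m for m in single_tags if METHODS[m][1] in ("PC", "BC")]
    mboot_tags = [m for m in multi_tags if METHODS[m][1] in ("PC", "BC")]
    mc_tags = [m for m in multi_tags if METHODS[m][1] == "MC"]
    need_lr_a = "LRaM" in cond.methods
    need_lr_ab = "LRdiffM" in cond.methods

    ind_targets = cond.ind_targets if cond.ind_targets is not None else (l1, l2)

    def targets_of(tag: str) -> tuple[str, ...]:
        return (DIFFERENCE,) if "diff" in tag else ind_targets

    # truth per (approach, target): the single-group difference is focal-ref
    def truth_of(tag: str, target: str) -> float:
        if target == DIFFERENCE:
            d = truths["difference"]
            return -d if METHODS[tag][0] == "single" else d
        return truths[target]

    interval_tags = sboot_tags + mboot_tags + mc_tags
    rec = {
        (tag, t): {"reject": [], "lower": [], "upper": []}
        for tag in interval_tags
        for t in targets_of(tag)
    }
    for tag in cond.methods:
        if METHODS[tag][1] == "test":
            rec[(tag, DIFFERENCE)] = {"reject": [], "lower": [], "upper": []}

    est_rows = {}  # parameter -> list of estimates

    def track(name, value):
        est_rows.setdefault(name, []).append(value)

    n_fail = 0
    for rep in range(cond.n_reps):
        try:
            data = generate_dataset(
                pop, cond.n_g1, cond.n_g2, seed=_rep_seed(cond.seed, rep, 0)
            )
            sfit = mfit = None
            if single_tags:
                sfit = fit_single_group(data, coding)
                track("a1", sfit.a1)
                track("a3", sfit.a3)
                track("b", sfit.b)
                eff = simple_indirect_effects(sfit)
                track(f"ind[{l1}]:S", eff.by_group[l1])
                track(f"ind[{l2}]:S", eff.by_group[l2])
                track("diff:S", eff.difference)
            if multi_tags:
                mfit = fit_multi_group(data, order=(l1, l2))
                meff = simple_indirect_effects(mfit)
                for lab in (l1, l2):
                    track(f"a[{lab}]", mfit.a(lab))
                    track(f"b[{lab}]", mfit.b(lab))
                    track(f"ind[{lab}]:M", meff.by_group[lab])
                track("diff:M", meff.difference)

            alpha = 1.0 - cond.level
            if "za3S" in cond.methods:
                rec[("za3S", DIFFERENCE)]["reject"].append(
                    z_test_a3(sfit).p_value < alpha
                )
            if "WdiffS" in cond.methods:
                rec[("WdiffS", DIFFERENCE)]["reject"].append(
                    wald_product_test(sfit).p_value < alpha
                )
            if "WdiffM" in cond.methods:
                rec[("WdiffM", DIFFERENCE)]["reject"].append(
                    wald_diff_test(mfit).p_value < alpha
                )
            if need_lr_a:
                cfit = fit_multi_group(data, {"a_equal"}, order=(l1, l2))
                rec[("LRaM", DIFFERENCE)]["reject"].append(
                    lr_test(mfit, cfit).p_value < alpha
                )
            if need_lr_ab:
                cfit = fit_multi_group(data, {"ab_product_equal"}, order=(l1, l2))
                rec[("LRdiffM", DIFFERENCE)]["reject"].append(
                    lr_test(mfit, cfit).p_value < alpha
                )

            if sboot_tags:
                tset = set()
                for tag in sboot_tags:
                    tset.update(targets_of(tag))
                draws = bootstrap_draw_sets(
                    data, tuple(sorted(tset)), approach="single", B=cond.B,
                    seed=_rep_seed(cond.seed, rep, 1), coding=coding,
                )
                for tag in sboot_tags:
                    fn = percentile_ci if METHODS[tag][1] == "PC" else bc_ci
                    for t in targets_of(tag):
                        ci = fn(draws[t], cond.level)
                        r = rec[(tag, t)]
                        r["reject"].append(ci_excludes_zero(ci))
                        r["lower"].append(ci.lower)
                        r["upper"].append(ci.upper)
            if mboot_tags:
                tset = set()
                for tag in mboot_tags:
                    tset.update(targets_of(tag))
                draws = bootstrap_draw_sets(
                    data, tuple(sorted(tset)), approach="multi", B=cond.B,
                    seed=_rep_seed(cond.seed, rep, 2), order=(l1, l2),
                )
                for tag in mboot_tags:
                    fn = percentile_ci if METHODS[tag][1] == "PC" else bc_ci
                    for t in targets_of(tag):
                        ci = fn(draws[t], cond.level)
                        r = rec[(tag, t)]
                        r["reject"].append(ci_excludes_zero(ci))
                        r["lower"].append(ci.lower)
                        r["upper"].append(ci.upper)
            if mc_tags:
                draws = monte_carlo_draws(
                    mfit, R=cond.R, seed=_rep_seed(cond.seed, rep, 3)
                )
                for tag in mc_tags:
                    for t in targets_of(tag):
                        ci = percentile_ci(draws[t], cond.level)
                        r = rec[(tag, t)]
                        r["reject"].append(ci_excludes_zero(ci))
                        r["lower"].append(ci.lower)
                        r["upper"].append(ci.upper)
        except Exception:
            n_fail += 1
            if n_fail > max(0.02 * cond.n_reps, 1):
                raise SimulationError(
                    f"{n_fail} of {rep + 1} replications failed in condition "
                    f"{pop.name} ({cond.n_g1},{cond.n_g2})"
                )

    rows = []
    for (tag, t), r in rec.items():
        n_used = len(r["reject"])
        p = float(np.mean(r["reject"])) if n_used else np.nan
        row = {
            "method": tag,
            "target": t,
            "truth": truth_of(tag, t),
            "n_used": n_used,
            "reject_rate": p,
            "mc_se": float(np.sqrt(p * (1 - p) / n_used)) if n_used else np.nan,
        }
        if r["lower"]:
            lo = np.array(r["lower"])
            hi = np.array(r["upper"])
            left, right, cover = miss_side_tally(lo, hi, row["truth"])
            row.update(
                coverage=cover / n_used,
                mean_width=float(np.mean(hi - lo)),
                left_miss=left,
                right_miss=right,
                left_right_ratio=(left / right) if right > 0 else np.nan,
                ratio_defined=right > 0,
            )
        else:
            row.update(
                coverage=np.nan, mean_width=np.nan, left_miss=0, right_miss=0,
                left_right_ratio=np.nan, ratio_defined=False,
            )
        rows.append(row)
    results = pd.DataFrame(rows).sort_values(["method", "target"]).reset_index(drop=True)

    bias_rows = []
    truth_map = {
        "a1": pop.groups[l1].a,
        "a3": pop.groups[l2].a - pop.groups[l1].a,
        "b": None,  # pooled; defined when both groups share b
        f"a[{l1}]": pop.groups[l1].a,
        f"a[{l2}]": pop.groups[l2].a,
        f"b[{l1}]": pop.groups[l1].b,
        f"b[{l2}]": pop.groups[l2].b,
        f"ind[{l1}]:S": truths[l1],
        f"ind[{l2}]:S": truths[l2],
        f"ind[{l1}]:M": truths[l1],
        f"ind[{l2}]:M": truths[l2],
        "diff:S": -truths["difference"],
        "diff:M": truths["difference"],
    }
    if pop.groups[l1].b == pop.groups[l2].b:
        truth_map["b"] = pop.groups[l1].b
    for name, vals in est_rows.items():
        mean = float(np.mean(vals))
        tv = truth_map.get(name)
        bias = mean - tv if tv is not None else np.nan
        bias_rows.append(
            {
                "parameter": name,
                "mean_estimate": mean,
                "truth": np.nan if tv is None else tv,
                "bias": bias,
                "relative_bias": (bias / tv) if tv not in (None, 0.0) else np.nan,
                "mc_se": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
            }
        )
    bias = pd.DataFrame(bias_rows)

    return SimulationSummary(
        population=pop.name,
        n_g1=cond.n_g1,
        n_g2=cond.n_g2,
        n_reps=cond.n_reps,
        seed=cond.seed,
        results=results,
        bias=bias,
        n_failures=n_fail,
    )


# ---------------------------------------------------------------------------
# table-shaped replication reports
# ---------------------------------------------------------------------------

_TABLE_SPECS = {
    "4": {"structural": "I", "methods": ("za3S", "LRaM"), "scope": "diff"},
    "5": {
        "structural": "I",
        "methods": ("WdiffS", "LRdiffM", "WdiffM", "PCdiffM", "BCdiffM", "MCdiffM"),
        "scope": "diff",
    },
    "6": {
        "structural": "II",
        "methods": ("PCindS", "BCindS", "PCindM", "BCindM", "MCindM"),
        "scope": "ind",
    },
}
_VARIANCE_ORDER = ("0", "M1", "M2", "M3", "Y1", "Y2", "Y3")


def _table_columns(methods):
    return ["population", "n_g1", "n_g2"] + [
        c for m in methods for c in (m, f"{m}_se")
    ]


def replicate_tables(config: dict) -> dict[str, pd.DataFrame]:
    """Reproduce the rejection-rate tables of the simulation study at a
    configurable scale.

    ``config`` keys: ``tables`` (subset of {"4","5","6","7"}), ``n_reps``,
    ``B``, ``R``, ``seed``, ``level``. Tables 4/5 report rejection rates for
    the group-difference methods under structural set I (Type I error);
    table 6 reports rejection rates for G1's null simple indirect effect
    under set II; table 7 reports average left/right miss ratios of the
    simple-indirect-effect intervals per structural set and group. Every rate
    column is paired with its Monte Carlo standard error. ``n_reps = 0``
    yields header-only tables.
    """
    tables = list(config.get("tables", []))
    n_reps = int(config.get("n_reps", 200))
    B = int(config.get("B", 200))
    R = int(config.get("R", 200))
    seed = int(config.get("seed", 0))
    level = float(config.get("level", 0.95))
    catalog = population_catalog()
    out = {}

    def run(pop_name, n1, n2, methods, ind_targets=None):
        cond = SimulationCondition(
            population=catalog[pop_name],
            n_g1=n1,
            n_g2=n2,
            n_reps=n_reps,
            methods=tuple(methods),
            seed=seed,
            B=B,
            R=R,
            level=level,
            ind_targets=ind_targets,
        )
        return run_condition(cond)

    for tnum in tables:
        if tnum in _TABLE_SPECS:
            spec = _TABLE_SPECS[tnum]
            methods = spec["methods"]
            cols = _table_columns(methods)
            rows = []
            if n_reps > 0:
                for n1, n2 in SIZE_PATTERNS:
                    for v in _VARIANCE_ORDER:
                        pname = f"{spec['structural']}-{v}"
                        ind = ("G1",) if spec["scope"] == "ind" else None
                        summ = run(pname, n1, n2, methods, ind_targets=ind)
                        target = "G1" if spec["scope"] == "ind" else DIFFERENCE
                        row = {"population": pname, "n_g1": n1, "n_g2": n2}
                        for m in methods:
                            r = summ.row(m, target)
                            row[m] = r["reject_rate"]
                            row[f"{m}_se"] = r["mc_se"]
                        rows.append(row)
            out[f"table{tnum}"] = pd.DataFrame(rows, columns=cols)
        elif tnum == "7":
            methods = ("PCindS", "BCindS", "PCindM", "BCindM", "MCindM")
            cols = ["method"] + [
                f"{s}_{g}" for s in ("I", "II", "III") for g in ("G1", "G2")
            ]
            rows = []
            if n_reps > 0:
                ratios = {(m, s, g): [] for m in methods for s in ("I", "II", "III") for g in ("G1", "G2")}
                for s in ("I", "II", "III"):
                    for v in _VARIANCE_ORDER:
                        for n1, n2 in SIZE_PATTERNS:
                            summ = run(f"{s}-{v}", n1, n2, methods)
                            for m in methods:
                                for g in ("G1", "G2"):
                                    r = summ.row(m, g)
                                    if r["ratio_defined"]:
                                        ratios[(m, s, g)].append(r["left_right_ratio"])
                for m in methods:
                    row = {"method": m}
                    for s in ("I", "II", "III"):
                        for g in ("G1", "G2"):
                            v = ratios[(m, s, g)]
                            row[f"{s}_{g}"] = float(np.mean(v)) if v else np.nan
                    rows.append(row)
            out["table7"] = pd.DataFrame(rows, columns=cols)
        else:
            raise ValueError(f"unknown table {tnum!r}")
    return out
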