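"""Analysis configuration, orchestration, and report serialization.

:class:`AnalysisConfig` collects everything needed to reproduce an analysis
(column mapping, coding, approach, constraints, methods, level, draw counts,
seed); :func:`run_analysis` executes the requested fits and methods and
returns a :class:`ReportBundle` that round-trips losslessly through JSON and
can be written as text (3-decimal table style), TSV, or full-precision JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data import GroupCoding, MediationDataset
from .errors import ConfigError
from .inference import (
    DIFFERENCE,
    IntervalEstimate,
    TestResult,
    bc_ci,
    bootstrap_draw_sets,
    lr_test,
    monte_carlo_draws,
    percentile_ci,
    wald_diff_test,
    wald_product_test,
    z_test_a3,
)
from .model import VALID_CONSTRAINTS, fit_multi_group, fit_single_group, simple_indirect_effects

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "write_report"]

# methods allowed per approach; generic interval tags get the S/M suffix from
# the approach
_SINGLE_METHODS = {"za3S", "WdiffS", "PCind", "BCind", "PCdiff", "BCdiff",
                   "PCindS", "BCindS", "PCdiffS", "BCdiffS"}
_MULTI_METHODS = {"LRaM", "LRdiffM", "WdiffM", "PCind", "BCind", "MCind",
                  "PCdiff", "BCdiff", "MCdiff", "PCindM", "BCindM", "MCindM",
                  "PCdiffM", "BCdiffM", "MCdiffM"}


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    x: str = "x"
    m: str = "m"
    y: str = "y"
    group: str = "group"
    reference: str | None = None
    focal: str | None = None
    approach: str = "multi"  # "single" | "multi"
    constraints: tuple[str, ...] = ()
    methods: tuple[str, ...] = ()
    level: float = 0.95
    B: int = 1000
    R: int = 1000
    seed: int | None = None
    resampling: str = "stratified"

    def __post_init__(self):
        self.constraints = tuple(self.constraints)
        self.methods = tuple(self.methods)
        if self.approach not in ("single", "multi"):
            raise ConfigError(f"unknown approach {self.approach!r}")
        bad = set(self.constraints) - VALID_CONSTRAINTS
        if bad:
            raise ConfigError(f"unknown constraints {sorted(bad)}")
        allowed = _SINGLE_METHODS if self.approach == "single" else _MULTI_METHODS
        for m in self.methods:
            if m not in allowed:
                raise ConfigError(
                    f"method {m!r} is not available with the {self.approach!r} approach"
                )
        if not 0.0 < self.level < 1.0:
            raise ConfigError("level must be in (0, 1)")

    @property
    def mapping(self) -> dict[str, str]:
        return {"x": self.x, "m": self.m, "y": self.y, "group": self.group}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReportBundle:
    """Fit summaries, estimates, test results, intervals, and provenance."""

    fits: dict
    estimates: dict
    tests: list[TestResult] = field(default_factory=list)
    intervals: list[IntervalEstimate] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fits": self.fits,
            "estimates": self.estimates,
            "tests": [t.to_dict() for t in self.tests],
            "intervals": [c.to_dict() for c in self.intervals],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        return cls(
            fits=d["fits"],
            estimates=d["estimates"],
            tests=[
                TestResult(
                    method=t["method"], statistic=t["statistic"],
                    df=t["df"], p_value=t["p_value"],
                )
                for t in d["tests"]
            ],
            intervals=[
                IntervalEstimate(
                    method=c["method"], target=c["target"], lower=c["lower"],
                    upper=c["upper"], level=c["level"], n_draws=c["n_draws"],
                    seed=c["seed"], flags=tuple(c["flags"]),
                )
                for c in d["intervals"]
            ],
            provenance=d["provenance"],
        )


def _resolve_tag(tag: str, approach: str) -> str:
    if tag in ("PCind", "BCind", "MCind", "PCdiff", "BCdiff", "MCdiff"):
        return tag + ("S" if approach == "single" else "M")
    return tag


def run_analysis(config: AnalysisConfig, data: MediationDataset) -> ReportBundle:
    """Run the configured fits and methods; always reports point estimates of
    both simple indirect effects and their difference.

    Wald tests, Monte Carlo draws, and bootstrap refits use the unconstrained
    parameterization; LR tests compare the configured baseline fit against
    the same fit with the tested constraint added.
    """
    coding = (
        GroupCoding(config.reference, config.focal)
        if config.reference and config.focal
        else data.default_coding()
    )
    if coding.reference not in data.labels or coding.focal not in data.labels:
        raise ConfigError(
            f"coding labels ({coding.reference!r}, {coding.focal!r}) not found in "
            f"data labels {data.labels}"
        )
    order = (coding.reference, coding.focal)
    methods = [_resolve_tag(m, config.approach) for m in config.methods]

    fits = {}
    tests: list[TestResult] = []
    intervals: list[IntervalEstimate] = []

    if config.approach == "single":
        sfit = fit_single_group(data, coding)
        eff = simple_indirect_effects(sfit)
        fits["single_group"] = sfit.to_dict()
        if "za3S" in methods:
            tests.append(z_test_a3(sfit))
        if "WdiffS" in methods:
            tests.append(wald_product_test(sfit))
        boot_tags = [m for m in methods if m[:2] in ("PC", "BC")]
        if boot_tags:
            targets = set()
            for m in boot_tags:
                targets.update((DIFFERENCE,) if "diff" in m else order)
            draws = bootstrap_draw_sets(
                data, tuple(sorted(targets)), approach="single", B=config.B,
                seed=config.seed, resampling=config.resampling, coding=coding,
            )
            for m in boot_tags:
                fn = percentile_ci if m.startswith("PC") else bc_ci
                for t in (DIFFERENCE,) if "diff" in m else order:
                    intervals.append(fn(draws[t], config.level))
    else:
        mfit_u = fit_multi_group(data, order=order)
        base = fit_multi_group(data, config.constraints, order=order) if config.constraints else mfit_u
        eff = simple_indirect_effects(base)
        fits["multi_group"] = base.to_dict()
        if config.constraints:
            fits["multi_group_unconstrained"] = mfit_u.to_dict()
        if "LRaM" in methods:
            c = fit_multi_group(
                data, set(config.constraints) | {"a_equal"}, order=order
            )
            tests.append(lr_test(base, c))
        if "LRdiffM" in methods:
            c = fit_multi_group(
                data, set(config.constraints) | {"ab_product_equal"}, order=order
            )
            tests.append(lr_test(base, c))
        if "WdiffM" in methods:
            tests.append(wald_diff_test(mfit_u))
        boot_tags = [m for m in methods if m[:2] in ("PC", "BC")]
        if boot_tags:
            targets = set()
            for m in boot_tags:
                targets.update((DIFFERENCE,) if "diff" in m else order)
            draws = bootstrap_draw_sets(
                data, tuple(sorted(targets)), approach="multi", B=config.B,
                seed=config.seed, order=order,
            )
            for m in boot_tags:
                fn = percentile_ci if m.startswith("PC") else bc_ci
                for t in (DIFFERENCE,) if "diff" in m else order:
                    intervals.append(fn(draws[t], config.level))
        mc_tags = [m for m in methods if m.startswith("MC")]
        if mc_tags:
            draws = monte_carlo_draws(mfit_u, R=config.R, seed=config.seed)
            for m in mc_tags:
                for t in (DIFFERENCE,) if "diff" in m else order:
                    intervals.append(percentile_ci(draws[t], config.level))

    estimates = {
        "simple_indirect": dict(eff.by_group),
        "difference": eff.difference,
        "convention": eff.convention,
        "source": eff.source,
    }
    provenance = {
        "package": "groupmediate",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    return ReportBundle(
        fits=fits, estimates=estimates, tests=tests, intervals=intervals,
        provenance=provenance,
    )


def _fmt3(v: float) -> str:
    return f"{v:.3f}"


def write_report(bundle: ReportBundle, path: str | Path, format: str = "text") -> Path:
    """Write the bundle as ``text`` (3-dp table style), ``json`` (full
    precision), or ``tsv`` (one row per method result)."""
    path = Path(path)
    try:
        if format == "json":
            path.write_text(json.dumps(bundle.to_dict(), indent=2) + "\n")
        elif format == "text":
            lines = ["# groupmediate report", ""]
            est = bundle.estimates
            for g, v in est["simple_indirect"].items():
                lines.append(f"simple indirect effect [{g}]: {_fmt3(v)}")
            lines.append(
                f"difference ({est['convention']}): {_fmt3(est['difference'])}"
            )
            lines.append("")
            for t in bundle.tests:
                df = "" if t.df is None else f", df = {t.df}"
                lines.append(
                    f"{t.method}: statistic = {_fmt3(t.statistic)}{df}, "
                    f"p = {t.p_value:.4f}"
                )
            for c in bundle.intervals:
                lines.append(
                    f"{c.method} {c.level:.0%} CI for {c.target}: "
                    f"({_fmt3(c.lower)}, {_fmt3(c.upper)})"
                )
            path.write_text("\n".join(lines) + "\n")
        elif format == "tsv":
            cols = ["method", "target", "statistic", "df", "p_value",
                    "lower", "upper", "level"]
            rows = [cols]
            for t in bundle.tests:
                rows.append([t.method, DIFFERENCE, repr(t.statistic),
                             "" if t.df is None else str(t.df),
                             repr(t.p_value), "", "", ""])
            for c in bundle.intervals:
                rows.append([c.method, c.target, "", "", "",
                             repr(c.lower), repr(c.upper), repr(c.level)])
            path.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        else:
            raise ConfigError(f"unknown report format {format!r}")
    except OSError as e:
        raise ConfigError(f"cannot write report to {path}: {e}") from e
    return path
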