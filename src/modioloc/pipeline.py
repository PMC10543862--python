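"""End-to-end workflow: a-priori criteria, method comparison, collocation.

The intended study flow is:

1. establish a-priori agreement criteria from two rater-style replicate sets
   (interrater Bland-Altman precision and ICC per parameter);
2. compare a candidate ("auto") method against the established ("manual")
   method: Bland-Altman bias/limits, percentage error, correlation, ICC,
   normality of the differences;
3. collocate the mid-modiolar axes per array (translation-only optimisation)
   and repeat the comparison on the collocated data;
4. judge the candidate method: bias is acceptable when its magnitude does not
   exceed the interrater precision for that parameter.

Per-array collocation shifts are applied to the moving set and the
electrode-level differences of all arrays are pooled into the post-collocation
statistics, mirroring the pooled pre-collocation analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .agreement import AgreementReport, build_agreement_report, paired_differences
from .collocation import (
    DEFAULT_N_STARTS,
    DEFAULT_SEARCH_BOUND_MM,
    DEFAULT_TOLERANCE,
    ShiftEstimate,
    optimize_shift,
)
from .errors import ConfigError, PairingError
from .measurement import (
    ElectrodeArrayMeasurement,
    read_measurements_csv,
    transform_measurement,
)
from .synthetic import SpiralCohortConfig

__all__ = [
    "AprioriCriteria",
    "ComparisonReport",
    "PipelineConfig",
    "run_apriori",
    "collocate_cohort",
    "run_comparison",
    "render_outputs",
]

PARAMETERS = ("EMD", "aDOI")


@dataclass(frozen=True)
class AprioriCriteria:
    """Interrater agreement criteria used to judge the method comparison.

    ``precision_*`` are the half-widths of the interrater limits of agreement
    (1.96 * SD of interrater differences); a candidate method's bias is deemed
    acceptable when it does not exceed them in magnitude.
    """

    precision_emd_mm: float
    precision_adoi_deg: float
    bias_emd_mm: float
    bias_adoi_deg: float
    icc_emd: float
    icc_adoi: float
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AprioriCriteria":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def precision_for(self, parameter: str) -> float:
        return {"EMD": self.precision_emd_mm,
                "aDOI": self.precision_adoi_deg}[parameter]


def run_apriori(rater_a: Iterable[ElectrodeArrayMeasurement],
                rater_b: Iterable[ElectrodeArrayMeasurement],
                seed: int | None = None) -> AprioriCriteria:
    """Interrater Bland-Altman precision and ICC from two manual-style sets."""
    rater_a = list(rater_a)
    rater_b = list(rater_b)
    reports = {p: build_agreement_report(rater_a, rater_b, p) for p in PARAMETERS}
    emd, adoi = reports["EMD"], reports["aDOI"]

    def half_width(rep: AgreementReport) -> float:
        return (rep.loa_high - rep.loa_low) / 2.0

    return AprioriCriteria(
        precision_emd_mm=half_width(emd),
        precision_adoi_deg=half_width(adoi),
        bias_emd_mm=emd.bias,
        bias_adoi_deg=adoi.bias,
        icc_emd=emd.icc,
        icc_adoi=adoi.icc,
        seed=seed,
    )


def _by_array(measurements: Iterable[ElectrodeArrayMeasurement]
              ) -> dict[str, ElectrodeArrayMeasurement]:
    out: dict[str, ElectrodeArrayMeasurement] = {}
    for m in measurements:
        if m.array_id in out:
            raise PairingError(f"duplicate array_id {m.array_id!r} in one set")
        out[m.array_id] = m
    return out


def collocate_cohort(moving: Iterable[ElectrodeArrayMeasurement],
                     fixed: Iterable[ElectrodeArrayMeasurement],
                     *,
                     search_bound: float = DEFAULT_SEARCH_BOUND_MM,
                     n_starts: int = DEFAULT_N_STARTS,
                     tolerance: float = DEFAULT_TOLERANCE,
                     ) -> tuple[list[ShiftEstimate], list[ElectrodeArrayMeasurement]]:
    """One shift per array: optimise the moving set toward the fixed set.

    Returns the per-array shift estimates and the transformed moving
    measurements (same array order as the moving input).
    """
    moving = list(moving)
    fixed_by_id = _by_array(fixed)
    missing = [m.array_id for m in moving if m.array_id not in fixed_by_id]
    if missing:
        raise PairingError(f"arrays missing from the fixed set: {missing}")
    shifts: list[ShiftEstimate] = []
    transformed: list[ElectrodeArrayMeasurement] = []
    for m in moving:
        est = optimize_shift(m, fixed_by_id[m.array_id],
                             search_bound=search_bound, n_starts=n_starts,
                             tolerance=tolerance)
        shifts.append(est)
        transformed.append(transform_measurement(m, est.shift))
    return shifts, transformed


@dataclass(frozen=True)
class ComparisonReport:
    """Pre- and (optionally) post-collocation agreement for both parameters."""

    pre: dict[str, AgreementReport]
    post: dict[str, AgreementReport] | None
    shifts: tuple[ShiftEstimate, ...] | None
    criteria: AprioriCriteria | None
    verdicts: dict[str, bool] | None
    loa_reduction_percent: dict[str, float] | None
    seed: int | None = None
    pairs_pre: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    pairs_post: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        out: dict = {
            "package_version": _version,
            "seed": self.seed,
            "pre": {p: r.to_dict() for p, r in self.pre.items()},
        }
        if self.post is not None:
            out["post"] = {p: r.to_dict() for p, r in self.post.items()}
            out["loa_reduction_percent"] = self.loa_reduction_percent
            out["shifts"] = [s.to_dict() for s in self.shifts or ()]
        if self.criteria is not None:
            out["criteria"] = asdict(self.criteria)
            out["verdicts"] = self.verdicts
        return out


def _half_width(rep: AgreementReport) -> float:
    return (rep.loa_high - rep.loa_low) / 2.0


def run_comparison(auto: Iterable[ElectrodeArrayMeasurement],
                   manual: Iterable[ElectrodeArrayMeasurement],
                   criteria: AprioriCriteria | None = None,
                   *,
                   with_collocation: bool = True,
                   search_bound: float = DEFAULT_SEARCH_BOUND_MM,
                   n_starts: int = DEFAULT_N_STARTS,
                   tolerance: float = DEFAULT_TOLERANCE,
                   confidence: float = 0.95,
                   seed: int | None = None) -> ComparisonReport:
    """Full method comparison of ``auto`` against the reference ``manual`` set.

    With collocation enabled, the auto set is the moving set: each array's
    coordinates are uniformly translated to best correlate with the manual
    measurements before the post-collocation statistics are computed.
    """
    auto = list(auto)
    manual = list(manual)
    pairs_pre = {p: paired_differences(auto, manual, p) for p in PARAMETERS}
    pre = {p: build_agreement_report(auto, manual, p, confidence=confidence)
           for p in PARAMETERS}

    post = shifts = None
    reduction = None
    pairs_post: dict[str, pd.DataFrame] = {}
    if with_collocation:
        shift_list, auto_t = collocate_cohort(
            auto, manual, search_bound=search_bound, n_starts=n_starts,
            tolerance=tolerance)
        shifts = tuple(shift_list)
        pairs_post = {p: paired_differences(auto_t, manual, p)
                      for p in PARAMETERS}
        post = {p: build_agreement_report(auto_t, manual, p,
                                          confidence=confidence)
                for p in PARAMETERS}
        # a zero pre-collocation width (self-comparison) leaves nothing to
        # reduce; report 0 rather than dividing by zero
        reduction = {
            p: (100.0 * (1.0 - _half_width(post[p]) / _half_width(pre[p]))
                if _half_width(pre[p]) > 0 else 0.0)
            for p in PARAMETERS}

    verdicts = None
    if criteria is not None:
        verdicts = {p: bool(abs(pre[p].bias) <= criteria.precision_for(p))
                    for p in PARAMETERS}

    return ComparisonReport(
        pre=pre, post=post, shifts=shifts, criteria=criteria,
        verdicts=verdicts, loa_reduction_percent=reduction, seed=seed,
        pairs_pre=pairs_pre, pairs_post=pairs_post,
    )


# ---------------------------------------------------------------------------
# configuration and rendering


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (file input XOR simulation)."""

    input_csv: str | None = None
    auto_label: str = "auto"
    manual_label: str = "manual"
    simulation: SpiralCohortConfig | None = None
    criteria_path: str | None = None
    with_collocation: bool = True
    search_bound: float = DEFAULT_SEARCH_BOUND_MM
    n_starts: int = DEFAULT_N_STARTS
    tolerance: float = DEFAULT_TOLERANCE
    confidence: float = 0.95
    output_dir: str = "modioloc_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigError(
                "provide exactly one of input_csv or a simulation config")
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must contain a mapping")
        data = dict(raw)
        sim = data.pop("simulation", None)
        if sim is not None:
            if "electrode_numbers" in sim:
                sim["electrode_numbers"] = tuple(sim["electrode_numbers"])
            try:
                sim = SpiralCohortConfig(**sim)
            except TypeError as exc:
                raise ConfigError(f"bad simulation config: {exc}") from exc
        data["simulation"] = sim
        data.update(overrides)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc

    def load_sets(self) -> tuple[list[ElectrodeArrayMeasurement],
                                 list[ElectrodeArrayMeasurement]]:
        """(auto, manual) measurement lists from file or simulation."""
        if self.input_csv is not None:
            measurements = read_measurements_csv(self.input_csv)
            auto = [m for m in measurements if m.method_label == self.auto_label]
            manual = [m for m in measurements
                      if m.method_label == self.manual_label]
            if not auto or not manual:
                raise PairingError(
                    f"input lacks method {self.auto_label!r} or "
                    f"{self.manual_label!r}")
            return auto, manual
        from .synthetic import generate_cohort
        cohort = generate_cohort(self.simulation)
        return list(cohort.auto), list(cohort.manual)


def render_outputs(report: ComparisonReport, outdir) -> list[str]:
    """Write plots, JSON and a human-readable summary; return file paths.

    A full run (with collocation) produces six plots — per-parameter scatter
    and Bland-Altman (pre/post panels), the per-electrode polar means and the
    per-array shift map — plus report.json and collocation_shifts.json.
    Without collocation the post panels, shift map and shift JSON are omitted
    and the summary says so.
    """
    from . import plots

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[str] = []

    report_path = outdir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    paths.append(str(report_path))

    if report.shifts is not None:
        from .collocation import shift_estimates_to_json
        shifts_path = outdir / "collocation_shifts.json"
        shift_estimates_to_json(report.shifts, shifts_path)
        paths.append(str(shifts_path))

    for p in PARAMETERS:
        paths.append(plots.scatter_plot(
            report.pairs_pre[p], p, outdir / f"scatter_{p.lower()}.png"))
        paths.append(plots.bland_altman_plot(
            report.pairs_pre[p], report.pre[p],
            report.pairs_post.get(p), (report.post or {}).get(p),
            p, outdir / f"bland_altman_{p.lower()}.png"))
    paths.append(plots.polar_means_plot(
        report.pairs_pre["EMD"], report.pairs_pre["aDOI"],
        outdir / "polar_means.png"))
    if report.shifts is not None:
        paths.append(plots.shift_map_plot(
            report.shifts, outdir / "collocation_shifts.png"))

    summary_path = outdir / "summary.txt"
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write(_summary_text(report))
    paths.append(str(summary_path))
    return paths


def _summary_text(report: ComparisonReport) -> str:
    lines = [f"modioloc {_version} method-comparison summary",
             f"seed: {report.seed}", ""]
    unit = {"EMD": "mm", "aDOI": "deg"}
    for p in PARAMETERS:
        r = report.pre[p]
        u = unit[p]
        lines.append(f"[{p}] n={r.n_pairs} pairs")
        lines.append(f"  pre-collocation:  bias {r.bias:+.3f} {u}, "
                     f"LoA [{r.loa_low:.3f}, {r.loa_high:.3f}] {u}, "
                     f"r={r.pearson_r:.3f} "
                     f"[{r.r_ci_low:.3f}, {r.r_ci_high:.3f}], "
                     f"ICC={r.icc:.3f}, "
                     f"percentage error {r.percentage_error:.1f}%")
        if report.post is not None:
            q = report.post[p]
            lines.append(f"  post-collocation: bias {q.bias:+.3f} {u}, "
                         f"LoA [{q.loa_low:.3f}, {q.loa_high:.3f}] {u}, "
                         f"r={q.pearson_r:.3f}")
            lines.append(f"  LoA half-width reduced by "
                         f"{report.loa_reduction_percent[p]:.1f}%")
        else:
            lines.append("  post-collocation: not computed "
                         "(collocation disabled)")
        if report.verdicts is not None:
            crit = report.criteria.precision_for(p)
            verdict = "PASS" if report.verdicts[p] else "FAIL"
            lines.append(f"  |bias| vs interrater precision "
                         f"(+/-{crit:.3f} {u}): {verdict}")
        lines.append("")
    return "\n".join(lines)
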