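"""Study-level orchestration: per-phase grey fits, pre/post comparison,
subject-subsample cross-validation, weekly summaries, and report rendering.

The pipeline composes the averaging stage (:mod:`greyhrv.data`) with the
GM(0,N) machinery (:mod:`greyhrv.grey`): per phase, average each subject's
weekly indices, assemble PSI as the major sequence against (TP, VLF, LF, HF),
and estimate the relationship weightings by least squares.  Comparing the
two phases — the weighting magnitudes and their ranking — is the study's
core readout: a large drop in the weighting scale after the intervention,
and HF rising to the top of the ranking, indicate enhanced parasympathetic
influence on the stress index.

Cross-validation refits both phases on random subject subsets of decreasing
size to probe the stability of the ranking; weekly summaries average each
index over subjects per week and phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import (
    AVERAGED_INDICES,
    HrvPanel,
    Phase,
    average_over_weeks,
    to_sequences,
)
from .grey import (
    InvalidInputError,
    RawSequence,
    UnderdeterminedSystemError,
    WeightingResult,
    build_design,
    solve_weights,
)

__all__ = [
    "PhaseComparison",
    "SubsampleReport",
    "WeeklySummary",
    "fit_phase",
    "compare_phases",
    "subsample_cv",
    "weekly_summary",
    "render_report",
]

#: minimum number of subjects for a stable 4-influence fit (L-1 >= 4 plus headroom)
MIN_SUBJECTS = 6

SUMMARY_INDICES = ("psi", "tp", "vlf", "lf", "hf", "lfhf")


@dataclass(frozen=True)
class PhaseComparison:
    """Pre- vs post-phase grey fits on the same panel."""

    before: WeightingResult
    after: WeightingResult
    weight_change: Mapping[str, float]  # |after| / |before| per factor, where defined
    rank_before: tuple[str, ...]
    rank_after: tuple[str, ...]

    @property
    def mean_before(self) -> float:
        return self.before.mean_magnitude

    @property
    def mean_after(self) -> float:
        return self.after.mean_magnitude


@dataclass(frozen=True)
class SubsampleEntry:
    size: int
    subjects: tuple[str, ...]
    before: WeightingResult
    after: WeightingResult


@dataclass(frozen=True)
class SubsampleReport:
    entries: tuple[SubsampleEntry, ...]
    sizes: tuple[int, ...]
    seed: int


@dataclass(frozen=True)
class WeeklySummary:
    """Mean (and SD) over subjects of each index, per week and phase."""

    means: Mapping[tuple[int, str], Mapping[str, float]]
    sds: Mapping[tuple[int, str], Mapping[str, float]]

    def mean(self, week: int, phase: Phase | str, index: str) -> float:
        return self.means[(week, Phase.parse(phase).value)][index]


def _fit_sequences(major: RawSequence, influences: list[RawSequence]) -> WeightingResult:
    return solve_weights(build_design(major, influences))


def fit_phase(panel: HrvPanel, phase: Phase | str) -> WeightingResult:
    """Average the panel over weeks in one phase and fit the GM(0,N) model."""
    if panel.n_subjects < MIN_SUBJECTS:
        raise UnderdeterminedSystemError(
            f"at least {MIN_SUBJECTS} subjects required for a 4-influence grey fit, "
            f"got {panel.n_subjects}"
        )
    table = average_over_weeks(panel, phase)
    major, influences = to_sequences(table)
    return _fit_sequences(major, influences)


def compare_phases(panel: HrvPanel) -> PhaseComparison:
    """Fit both phases and compare weighting magnitudes and rankings."""
    before = fit_phase(panel, Phase.PRE)
    after = fit_phase(panel, Phase.POST)
    change = {
        f: abs(after.weights[f]) / abs(before.weights[f])
        for f in before.weights
        if before.weights[f] != 0
    }
    return PhaseComparison(
        before=before,
        after=after,
        weight_change=change,
        rank_before=before.ranking,
        rank_after=after.ranking,
    )


def _subpanel(panel: HrvPanel, subjects: Sequence[str]) -> HrvPanel:
    chosen = set(subjects)
    return HrvPanel(r for r in panel.records if r.subject_id in chosen)


def subsample_cv(panel: HrvPanel, sizes: Sequence[int], seed: int) -> SubsampleReport:
    """Refit both phases on random subject subsets of the requested sizes.

    For each size one uniform subset is drawn without replacement; the same
    subset serves the pre and post fits so the phases stay comparable.  A
    size equal to the panel's subject count uses all subjects (no sampling).
    Panel row order is preserved within each subset, and results are fully
    reproducible from the seed.
    """
    n = panel.n_subjects
    for size in sizes:
        if size > n or size < MIN_SUBJECTS:
            raise InvalidInputError(
                f"subsample size {size} out of range [{MIN_SUBJECTS}, {n}]"
            )
    rng = np.random.default_rng(seed)
    entries = []
    for size in sizes:
        if size == n:
            subjects = panel.subjects
        else:
            idx = np.sort(rng.choice(n, size=size, replace=False))
            subjects = tuple(panel.subjects[i] for i in idx)
        sub = _subpanel(panel, subjects)
        entries.append(
            SubsampleEntry(
                size=size,
                subjects=subjects,
                before=fit_phase(sub, Phase.PRE),
                after=fit_phase(sub, Phase.POST),
            )
        )
    return SubsampleReport(entries=tuple(entries), sizes=tuple(sizes), seed=seed)


def weekly_summary(panel: HrvPanel) -> WeeklySummary:
    """Mean over subjects of each index per (week, phase); SDs kept alongside."""
    if len(panel) == 0:
        raise InvalidInputError("panel is empty")
    means: dict[tuple[int, str], dict[str, float]] = {}
    sds: dict[tuple[int, str], dict[str, float]] = {}
    for week in (1, 2, 3, 4):
        for phase in ("pre", "post"):
            vals = [
                r for r in panel.records if r.week == week and r.phase.value == phase
            ]
            if not vals:
                continue
            means[(week, phase)] = {
                k: float(np.mean([getattr(r, k) for r in vals])) for k in SUMMARY_INDICES
            }
            sds[(week, phase)] = {
                k: float(np.std([getattr(r, k) for r in vals], ddof=1)) if len(vals) > 1 else 0.0
                for k in SUMMARY_INDICES
            }
    return WeeklySummary(means=means, sds=sds)


def _psi_reduction_candidates(summary: WeeklySummary) -> dict[str, float]:
    """Candidate percent-reduction definitions for the weekly PSI effect.

    Several plausible arithmetic readings of "average PSI relaxation" are
    reported side by side; none is privileged.
    """
    out: dict[str, float] = {}
    weeks = sorted({w for (w, p) in summary.means if p == "pre"})
    pre = [summary.means[(w, "pre")]["psi"] for w in weeks]
    post = [summary.means[(w, "post")]["psi"] for w in weeks]
    if pre and post:
        per_week = [100.0 * (a - b) / a for a, b in zip(pre, post) if a > 0]
        out["mean_weekly_pct_drop_pre_to_post"] = float(np.mean(per_week))
        out["pct_drop_of_mean_psi"] = 100.0 * (np.mean(pre) - np.mean(post)) / np.mean(pre)
        if pre[0] > 0:
            out["pct_drop_week1_pre_to_week_last_post"] = 100.0 * (pre[0] - post[-1]) / pre[0]
        if max(pre) > 0:
            out["pct_drop_max_pre_to_min_pre"] = 100.0 * (max(pre) - min(pre)) / max(pre)
    return out


def _weighting_block(result: WeightingResult, decimals: int = 4) -> dict:
    return {
        "weights_signed": {k: round(v, decimals) for k, v in result.weights.items()},
        "weights": {k: round(v, decimals) for k, v in result.magnitudes.items()},
        "mean_weighting": round(result.mean_magnitude, decimals),
        "ranking": list(result.ranking),
        "residual_norm": result.residual_norm,
        "n_samples": result.n_samples,
    }


def render_report(
    comparison: PhaseComparison | None,
    cv_report: SubsampleReport | None,
    summary: WeeklySummary | None,
    decimals: int = 4,
) -> tuple[str, str]:
    """Render a structured analysis report.

    Returns ``(json_text, markdown_text)``.  Weightings appear at 4 decimals
    (magnitudes, as conventionally tabulated, with signed values alongside),
    weekly means at 1 decimal.  Rendering is deterministic: identical inputs
    give byte-identical JSON.
    """
    doc: dict = {"generator": "greyhrv", "sections": []}
    md: list[str] = ["# Grey GM(0,N) HRV analysis report", ""]

    if comparison is not None:
        doc["comparison"] = {
            "before": _weighting_block(comparison.before, decimals),
            "after": _weighting_block(comparison.after, decimals),
            "weight_change": {k: round(v, decimals) for k, v in comparison.weight_change.items()},
            "rank_before": list(comparison.rank_before),
            "rank_after": list(comparison.rank_after),
        }
        doc["sections"].append("comparison")
        factors = list(comparison.before.weights)
        md += ["## Relationship weightings (|lambda|)", ""]
        md.append("| Phase | " + " | ".join(factors) + " |")
        md.append("|---" * (len(factors) + 1) + "|")
        for name, res in [("Before", comparison.before), ("After", comparison.after)]:
            md.append(
                f"| {name} | "
                + " | ".join(f"{res.magnitudes[f]:.{decimals}f}" for f in factors)
                + " |"
            )
        md += [
            "",
            f"Ranking before: {' > '.join(comparison.rank_before)}",
            f"Ranking after:  {' > '.join(comparison.rank_after)}",
            f"Mean weighting before/after: {comparison.mean_before:.{decimals}f} / "
            f"{comparison.mean_after:.{decimals}f}",
            "",
        ]

    if cv_report is not None and cv_report.entries:
        doc["cross_validation"] = {
            "seed": cv_report.seed,
            "sizes": list(cv_report.sizes),
            "entries": [
                {
                    "size": e.size,
                    "subjects": list(e.subjects),
                    "before": _weighting_block(e.before, decimals),
                    "after": _weighting_block(e.after, decimals),
                }
                for e in cv_report.entries
            ],
        }
        doc["sections"].append("cross_validation")
        md += ["## Subsample cross-validation", ""]
        for e in cv_report.entries:
            md.append(
                f"- L' = {e.size}: rank after = {' > '.join(e.after.ranking)}; "
                f"mean weighting before/after = {e.before.mean_magnitude:.{decimals}f} / "
                f"{e.after.mean_magnitude:.{decimals}f}"
            )
        md.append("")
    elif cv_report is not None:
        import logging

        logging.getLogger("greyhrv").info("cross-validation report empty; section omitted")

    if summary is not None:
        doc["weekly_summary"] = {
            "means": {
                f"week{w}_{p}": {k: round(v, 1) for k, v in row.items()}
                for (w, p), row in sorted(summary.means.items())
            },
            "sds": {
                f"week{w}_{p}": {k: round(v, 2) for k, v in row.items()}
                for (w, p), row in sorted(summary.sds.items())
            },
            "psi_reduction_candidates_pct": {
                k: round(v, 1) for k, v in _psi_reduction_candidates(summary).items()
            },
        }
        doc["sections"].append("weekly_summary")
        md += ["## Weekly means", ""]
        md.append("| Week | Phase | " + " | ".join(k.upper() for k in SUMMARY_INDICES) + " |")
        md.append("|---" * (len(SUMMARY_INDICES) + 2) + "|")
        for (w, p), row in sorted(summary.means.items()):
            md.append(
                f"| {w} | {p} | " + " | ".join(f"{row[k]:.1f}" for k in SUMMARY_INDICES) + " |"
            )
        md.append("")

    return json.dumps(doc, indent=2, sort_keys=True), "\n".join(md)
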