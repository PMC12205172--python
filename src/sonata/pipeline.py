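"""End-to-end orchestration: diagnose a modality, emit alternatives.

The pipeline mirrors how a practitioner uses the tool: (i) build the
manifold and self-align the chosen modality against variational copies,
(ii) call significant ambiguous cell pairs against the antitonic null,
(iii) aggregate them into substitutable groups, and (iv) if a
cross-modality integration (external or the built-in GW baseline) is at
hand, emit one alternative solution per confused group pair.

A dataset is *flagged ambiguous* when the significant-pair fraction
exceeds ``ambiguous_fraction_threshold`` (default ``2 * alpha``): below
that, the calls are indistinguishable from the test's false-positive
budget and the integration is reported unambiguous.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alternatives import AlternativeSolution, generate_alternatives
from .ambiguity import AmbiguityResult, NullSpline, ambiguity_pvalues, fit_null_spline
from .groups import AmbiguousGroupSet, find_ambiguous_groups
from .io import RunConfig, read_coupling, read_matrix, write_coupling, write_matrix
from .manifold import ModalityData
from .selfalign import Coupling, SelfAlignmentEnsemble, cross_modality_align, self_align

__all__ = ["DiagnosisReport", "diagnose", "run_pipeline"]

logger = logging.getLogger("sonata")


@dataclass
class DiagnosisReport:
    """Everything the ambiguity diagnosis of one modality produced."""

    ensemble: SelfAlignmentEnsemble
    spline: NullSpline
    result: AmbiguityResult
    groups: AmbiguousGroupSet
    flagged_ambiguous: bool
    config: RunConfig

    @property
    def n_groups(self) -> int:
        return self.groups.chosen_n_groups if self.flagged_ambiguous else 0

    def summary(self) -> str:
        lines = [
            f"cells: {self.ensemble.consensus.shape[0]}",
            f"significant ambiguous pairs: {int(self.result.significant.sum())} "
            f"of {self.result.n_pairs} "
            f"({100 * self.result.significant_fraction:.2f}%)",
        ]
        if self.flagged_ambiguous:
            lines.append(
                f"integration FLAGGED AS AMBIGUOUS: {self.n_groups} "
                "substitutable cell groups"
            )
        else:
            lines.append("integration not flagged as ambiguous")
        return "\n".join(lines)


def _stage(name: str, t0: float) -> None:
    logger.info("stage=%s elapsed=%.1fs", name, time.time() - t0)


def diagnose(data: ModalityData, config: RunConfig | None = None) -> DiagnosisReport:
    """Run self-alignment, ambiguity calling, and grouping on one modality."""
    cfg = config or RunConfig()
    t0 = time.time()
    ensemble = self_align(
        data,
        n_replicates=cfg.n_replicates,
        noise_sd=cfg.noise_sd,
        k_schedule=cfg.k_schedule,
        epsilon=cfg.epsilon,
        seed=cfg.seed,
        source_k=cfg.source_k,
    )
    _stage("self_align", t0)
    spline = fit_null_spline(ensemble.consensus, ensemble.source_geodesic)
    result = ambiguity_pvalues(
        ensemble.consensus,
        ensemble.source_geodesic,
        spline,
        alpha=cfg.alpha,
        local_quantile=cfg.local_quantile,
        min_fold_change=cfg.min_fold_change,
    )
    _stage("ambiguity_pvalues", t0)
    flagged = result.significant_fraction > cfg.ambiguous_fraction_threshold
    if flagged:
        groups = find_ambiguous_groups(
            result, ensemble.source_geodesic, Kmax=cfg.kmax, seed=cfg.seed
        )
    else:
        groups = AmbiguousGroupSet(
            assignment=np.full(data.n_cells, -1), chosen_n_groups=0
        )
    _stage("find_ambiguous_groups", t0)
    return DiagnosisReport(
        ensemble=ensemble,
        spline=spline,
        result=result,
        groups=groups,
        flagged_ambiguous=flagged,
        config=cfg,
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-driven pipeline; writes all artifacts plus a readable summary.

    Requires ``config.data_x``.  With ``config.data_y`` the built-in GW
    baseline integrates the pair; with ``config.coupling_xy`` an external
    integration is diagnosed instead.  Alternative solutions are written
    only when the dataset is flagged ambiguous.
    """
    if not config.data_x:
        raise ValueError("config.data_x is required")
    for path in (config.data_x, config.data_y, config.coupling_xy):
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    stage = "load"
    try:
        data_x = read_matrix(config.data_x, labels=config.labels_x)
        data_y = read_matrix(config.data_y, labels=config.labels_y) if config.data_y else None

        stage = "diagnose"
        report = diagnose(data_x, config)
        np.savetxt(out / "consensus.tsv", report.ensemble.consensus, delimiter="\t", fmt="%.12g")
        write_matrix(report.ensemble.source_geodesic.dist, out / "geodesic_x.tsv")
        (out / "null_spline.json").write_text(report.spline.to_json())
        report.result.to_frame().to_csv(out / "ambiguity_pairs.tsv", sep="\t", index=False)
        np.savetxt(
            out / "groups.tsv",
            np.column_stack([np.arange(data_x.n_cells), report.groups.assignment]),
            delimiter="\t",
            fmt="%d",
            header="cell_index\tgroup_id",
            comments="",
        )
        if report.groups.elbow is not None:
            np.savetxt(
                out / "elbow.tsv",
                np.column_stack(
                    [report.groups.elbow.n_groups_tried, report.groups.elbow.violations]
                ),
                delimiter="\t",
                fmt="%d",
                header="n_groups\tviolations",
                comments="",
            )

        stage = "integrate"
        gamma_xy: Coupling | None = None
        if config.coupling_xy:
            gamma_xy = read_coupling(config.coupling_xy)
        elif data_y is not None:
            gamma_xy = cross_modality_align(
                data_x, data_y, epsilon=config.epsilon, seed=config.seed
            )
            write_coupling(gamma_xy, out / "coupling_xy.tsv")

        stage = "alternatives"
        candidates: list[AlternativeSolution] = []
        if gamma_xy is not None:
            if report.flagged_ambiguous:
                candidates = generate_alternatives(
                    report.groups,
                    report.ensemble.consensus,
                    gamma_xy,
                    null_spline=report.spline,
                    geodesic=report.ensemble.source_geodesic,
                )
            else:
                candidates = generate_alternatives(
                    AmbiguousGroupSet(
                        assignment=np.full(data_x.n_cells, -1), chosen_n_groups=0
                    ),
                    report.ensemble.consensus,
                    gamma_xy,
                )
            for cand in candidates:
                if cand.name != "original":
                    s, t = cand.swapped_groups
                    np.savetxt(
                        out / f"alt_{s}_{t}.tsv", cand.gamma_alt, delimiter="\t", fmt="%.12g"
                    )
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise

    summary = report.summary()
    if gamma_xy is not None:
        summary += f"\ncandidate integration solutions: {max(len(candidates), 1)}"
    (out / "summary.txt").write_text(summary + "\n")

    return {
        "flagged_ambiguous": report.flagged_ambiguous,
        "n_groups": report.n_groups,
        "significant_fraction": report.result.significant_fraction,
        "n_candidates": len(candidates) if candidates else (1 if gamma_xy is not None else 0),
        "out_dir": str(out),
        "summary": summary,
    }
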