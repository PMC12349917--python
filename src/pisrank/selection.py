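"""Model ranking, the dual-branch ligand/ion decision, and input prep.

The pipeline runs the predictor twice when ligands or ions are present:
once with them ("holo" branch) and once with them stripped ("apo"
branch). The best model of each branch — best by the clash-augmented
interface-confidence ranking — is compared and the branch with the
higher score wins, so ligand information is only kept when it actually
improves interface confidence. The prep transforms rewrite a job
specification for the second branch: MSAs and templates are preserved
verbatim so no feature recomputation is needed; this toolkit does not
itself run inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import AlignmentError
from .model_io import JobSpec
from .scoring import ScoreReport

__all__ = [
    "BranchDecision",
    "rank_models",
    "decide_branch",
    "strip_paired_msa",
    "strip_ligands_ions",
    "audit_decisions",
]

APO_SUFFIX = "_apo"


def rank_models(reports: Sequence[ScoreReport]) -> list[ScoreReport]:
    """Order models by descending ranking score.

    Ties are broken by descending piTM, then ascending model id, so the
    ordering is a deterministic total order.
    """
    if not reports:
        raise ValueError("cannot rank an empty model list")
    return sorted(reports, key=lambda r: (-r.ranking_score, -r.pitm, r.model_id))


@dataclass
class BranchDecision:
    """Outcome of comparing the with-ligand and without-ligand branches."""

    with_ligand_best: ScoreReport
    without_ligand_best: ScoreReport
    chosen: str  # "with" | "without"
    pis_margin: float  # chosen minus rejected, on the ranking score
    job_id: Optional[str] = None

    @property
    def chosen_report(self) -> ScoreReport:
        return self.with_ligand_best if self.chosen == "with" else self.without_ligand_best

    def to_dict(self) -> dict:
        return {
            "job": self.job_id,
            "chosen": self.chosen,
            "pis_with": self.with_ligand_best.pis,
            "pis_without": self.without_ligand_best.pis,
            "score_with": self.with_ligand_best.ranking_score,
            "score_without": self.without_ligand_best.ranking_score,
            "margin": self.pis_margin,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def decide_branch(
    with_ligand: Sequence[ScoreReport],
    without_ligand: Sequence[ScoreReport],
    job_id: Optional[str] = None,
) -> BranchDecision:
    """Pick the branch whose best model has the higher ranking score.

    Comparison uses the clash-augmented ranking score, so a clashing
    "best" cannot beat a clash-free alternative. An exact tie resolves
    to the with-ligand branch, the information-richer default.
    """
    if not with_ligand or not without_ligand:
        raise ValueError("both branches need at least one scored model")
    best_with = rank_models(with_ligand)[0]
    best_without = rank_models(without_ligand)[0]
    if best_with.ranking_score >= best_without.ranking_score:
        chosen = "with"
        margin = best_with.ranking_score - best_without.ranking_score
    else:
        chosen = "without"
        margin = best_without.ranking_score - best_with.ranking_score
    return BranchDecision(
        with_ligand_best=best_with,
        without_ligand_best=best_without,
        chosen=chosen,
        pis_margin=margin,
        job_id=job_id,
    )


def strip_paired_msa(spec: JobSpec) -> JobSpec:
    """Disable MSA pairing: set every polymer's paired MSA to the empty
    alignment (the sentinel meaning "do not pair"). Unpaired MSAs and
    all other fields are untouched. Idempotent."""
    polymers = tuple(replace(p, paired_msa="") for p in spec.polymers)
    return replace(spec, polymers=polymers)


def strip_ligands_ions(spec: JobSpec) -> JobSpec:
    """Produce the apo-branch job: drop all ligands and ions.

    Polymers, MSAs, templates and the seed are unchanged so already
    generated features can be reused; the job name gains an "_apo"
    suffix (once — the transform is idempotent modulo that suffix).
    """
    name = spec.job_name
    if not name.endswith(APO_SUFFIX):
        name = name + APO_SUFFIX
    return replace(spec, job_name=name, ligands=(), ions=())


def audit_decisions(
    decisions: Sequence[BranchDecision],
    eval_scores: dict[str, tuple[float, float]],
    thresholds: Sequence[float] = (0.0, 0.01, 0.05),
) -> list[dict]:
    """Audit branch decisions against ground-truth DockQ values.

    ``eval_scores`` maps each decision's job id to the pair
    (dockq_with, dockq_without). For every threshold t the audit keeps
    the decisions whose absolute branch DockQ difference is >= t
    ("consequential" changes) and reports how often the chosen branch
    was the better one, plus the mean absolute DockQ difference among
    the qualifying cases (absent when none qualify).
    """
    rows: list[tuple[str, float, float]] = []
    for dec in decisions:
        if dec.job_id is None or dec.job_id not in eval_scores:
            raise AlignmentError(
                f"decision {dec.job_id!r} has no paired DockQ evaluation"
            )
        dq_with, dq_without = eval_scores[dec.job_id]
        rows.append((dec.chosen, dq_with, dq_without))
    table: list[dict] = []
    for t in thresholds:
        qualifying = [r for r in rows if abs(r[1] - r[2]) >= t]
        n = len(qualifying)
        correct = sum(
            1
            for chosen, dq_w, dq_wo in qualifying
            if (dq_w >= dq_wo) == (chosen == "with")
        )
        table.append(
            {
                "threshold": t,
                "n_qualifying": n,
                "n_chosen_better": correct,
                "correct_fraction": correct / n if n else None,
                "mean_abs_dockq_gain": (
                    sum(abs(r[1] - r[2]) for r in qualifying) / n if n else None
                ),
            }
        )
    return table
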