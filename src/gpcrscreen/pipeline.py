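"""End-to-end screening funnel: dock-score triage to ranked candidates.

Stages, applied in order to a scored candidate library:

1. ``top_fraction`` — keep the best-scoring fraction (default top 1 %)
   by each molecule's best (most negative) docking score;
2. ``prob_pass``    — random-forest antagonist probability filter
   (mean over poses, boundary-inclusive cutoff, default 0.84);
3. ``affinity_pass`` — predicted-affinity gate (pKd >= 5.5 by default);
4. ``clustered``    — Tanimoto-distance hierarchical clustering with
   silhouette-chosen k; cluster medoids become representatives;
5. ``simulated``    — cAMP dose-response simulation per representative,
   Hill-fit potency, novelty annotation against a reference set, and
   final ranking by (antagonist probability, potency).

Every molecule records the terminal stage it reached, so the funnel is
auditable; with a fixed seed the whole run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cascade as casc
from . import classify, diversity
from .chemfp import BitFingerprint, bulk_tanimoto


class Stage(IntEnum):
    SCORED = 0
    TOP_FRACTION = 1
    PROB_PASS = 2
    AFFINITY_PASS = 3
    CLUSTERED = 4
    SIMULATED = 5


@dataclass
class PipelineConfig:
    top_fraction: float = 0.01
    probability_threshold: float = 0.84
    min_pKd: float = 5.5
    cluster_k: Optional[int] = None          # fixed k; None -> silhouette
    cluster_k_range: tuple[int, int] = (2, 10)
    novelty_threshold: float = 0.4
    trees: int = 500
    seed: int = 0
    dose_mode: str = "antagonist"
    t_end: float = 100.0
    n_steps: int = 1000
    agonist_tone_pKd: float = 7.0            # reference agonist for tone

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must lie in [0, 1]")
        if not 0.0 <= self.novelty_threshold <= 1.0:
            raise ValueError("novelty_threshold must lie in [0, 1]")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ScreeningInputs:
    """Everything the funnel consumes, in memory.

    Pose-level classifier features (``pose_features`` rows aligned with
    ``pose_groups``) serve both training (labeled molecules) and
    prediction; ``fingerprints`` are molecule-level bit vectors for
    clustering and novelty.
    """

    molecule_ids: list[str]
    best_scores: np.ndarray              # per molecule, more negative = better
    pose_features: np.ndarray            # (n_poses, d)
    pose_groups: np.ndarray              # molecule id per pose row
    pkd: np.ndarray                      # predicted pKd per molecule
    fingerprints: np.ndarray             # (n_molecules, n_bits) bool
    train_X: np.ndarray                  # labeled training poses
    train_y: np.ndarray
    reference_fingerprints: np.ndarray   # (n_refs, n_bits) novelty reference


@dataclass
class CandidateRecord:
    molecule_id: str
    best_score: float
    stage_reached: Stage
    antagonist_probability: Optional[float] = None
    predicted_pKd: Optional[float] = None
    cluster_id: Optional[int] = None
    representative: bool = False
    novelty_tc: Optional[float] = None
    novel: Optional[bool] = None
    x50_uM: Optional[float] = None
    amplitude_uM: Optional[float] = None
    rank: Optional[int] = None


class EmptyFunnelError(RuntimeError):
    """A stage removed every remaining candidate."""


def inputs_from_synthetic(lib, seed: int = 0, n_reference: int = 20,
                          score_state: str = "inactive") -> "ScreeningInputs":
    """Assemble pipeline inputs from a generated two-class library.

    The top-fraction stage ranks by the best score against the chosen
    receptor state (antagonist screens dock against the inactive state);
    the novelty reference set is a random subset of the library's own
    fingerprints.
    """
    rng = np.random.default_rng(seed)
    ref = lib.ecfp[rng.choice(len(lib.ecfp),
                              size=min(n_reference, len(lib.ecfp)),
                              replace=False)]
    return ScreeningInputs(
        molecule_ids=lib.molecule_ids,
        best_scores=lib.best_scores_for_state(score_state),
        pose_features=lib.X, pose_groups=lib.sample_groups, pkd=lib.pkd,
        fingerprints=lib.ecfp, train_X=lib.X, train_y=lib.sample_labels,
        reference_fingerprints=ref)


def select_top_fraction(molecule_ids: Sequence[str], best_scores: np.ndarray,
                        fraction: float = 0.01) -> list[int]:
    """Indices of the ceil(fraction * n) best-scoring molecules.

    Docking scores are energies: most negative wins.  Ties at the cut
    break by molecule id.
    """
    n = len(molecule_ids)
    if n == 0:
        raise ValueError("empty input")
    keep = max(1, math.ceil(fraction * n))
    order = sorted(range(n), key=lambda i: (best_scores[i], molecule_ids[i]))
    return sorted(order[:keep])


@dataclass
class PipelineResult:
    records: list[CandidateRecord]
    funnel: dict[str, int]
    manifest: dict
    empty_stage: Optional[str] = None

    @property
    def final(self) -> list[CandidateRecord]:
        return sorted((r for r in self.records if r.rank is not None),
                      key=lambda r: r.rank)  # type: ignore[arg-type, return-value]


def run_pipeline(inputs: ScreeningInputs, config: PipelineConfig
                 ) -> PipelineResult:
    """Run the full filter cascade and rank the survivors.

    Stages empty of candidates terminate the funnel early; the report is
    still produced, flagged via ``empty_stage``.
    """
    cfg = config
    n = len(inputs.molecule_ids)
    records = {m: CandidateRecord(molecule_id=m,
                                  best_score=float(inputs.best_scores[i]),
                                  predicted_pKd=float(inputs.pkd[i]),
                                  stage_reached=Stage.SCORED)
               for i, m in enumerate(inputs.molecule_ids)}
    funnel: dict[str, int] = {"scored": n}

    # stage 1: top docking-score fraction
    keep_idx = select_top_fraction(inputs.molecule_ids, inputs.best_scores,
                                   cfg.top_fraction)
    survivors = [inputs.molecule_ids[i] for i in keep_idx]
    for m in survivors:
        records[m].stage_reached = Stage.TOP_FRACTION
    funnel["top_fraction"] = len(survivors)

    # stage 2: antagonist-probability filter
    model = classify.train_rf(inputs.train_X, inputs.train_y,
                              trees=cfg.trees, seed=cfg.seed)
    probs = []
    for m in survivors:
        rows = inputs.pose_features[inputs.pose_groups == m]
        p = classify.predict_molecule_probability(model, rows)
        records[m].antagonist_probability = p
        probs.append(p)
    kept = classify.filter_by_probability(probs, cfg.probability_threshold)
    survivors = [survivors[i] for i in kept]
    for m in survivors:
        records[m].stage_reached = Stage.PROB_PASS
    funnel["prob_pass"] = len(survivors)
    if not survivors:
        return _finish(records, funnel, cfg, "prob_pass")

    # stage 3: affinity gate
    idx_of = {m: i for i, m in enumerate(inputs.molecule_ids)}
    pkds = [float(inputs.pkd[idx_of[m]]) for m in survivors]
    kept = casc.affinity_gate(pkds, cfg.min_pKd)
    survivors = [survivors[i] for i in kept]
    for m in survivors:
        records[m].stage_reached = Stage.AFFINITY_PASS
    funnel["affinity_pass"] = len(survivors)
    if not survivors:
        return _finish(records, funnel, cfg, "affinity_pass")

    # stage 4: diversity clustering + medoid representatives
    fps = [BitFingerprint(bits=inputs.fingerprints[idx_of[m]], radius=2,
                          molecule_id=m) for m in survivors]
    if len(fps) >= 3:
        dm = diversity.tanimoto_distance_matrix(fps)
        if cfg.cluster_k is not None:
            k = min(cfg.cluster_k, len(fps) - 1)
            assignment = diversity.cluster_hierarchical(dm, max(2, k))
        else:
            lo, hi = cfg.cluster_k_range
            ks = range(max(2, lo), min(hi, len(fps) - 1) + 1)
            assignment = diversity.select_k_by_silhouette(dm, ks)
        reps = set(assignment.representatives)
        for m, c in zip(survivors, assignment.labels):
            records[m].cluster_id = int(c)
            records[m].stage_reached = Stage.CLUSTERED
            records[m].representative = m in reps
        funnel["clustered"] = len(survivors)
        survivors = [m for m in survivors if m in reps]
    else:  # too few to cluster: everyone is a singleton representative
        for c, m in enumerate(survivors):
            records[m].cluster_id = c
            records[m].representative = True
            records[m].stage_reached = Stage.CLUSTERED
        funnel["clustered"] = len(survivors)

    # stage 5: dose-response simulation + novelty + rank
    tone_aff = casc.Affinity(cfg.agonist_tone_pKd)
    params = casc.CascadeParameters(
        agonist_tone=(casc.agonist_ec80_uM(casc.CascadeParameters(), tone_aff),
                      cfg.agonist_tone_pKd))
    ref = inputs.reference_fingerprints
    sims = bulk_tanimoto(np.vstack([inputs.fingerprints[[idx_of[m] for m in survivors]],
                                    ref]))[:len(survivors), len(survivors):]
    for j, m in enumerate(survivors):
        aff = casc.Affinity(float(inputs.pkd[idx_of[m]]))
        curve = casc.dose_response(params, aff, mode=cfg.dose_mode,
                                   t_end=cfg.t_end, n_steps=cfg.n_steps,
                                   molecule_id=m)
        rec = records[m]
        fitres = curve.hill_fit
        if fitres is not None and not fitres.degenerate:
            rec.x50_uM = fitres.x50_uM
            rec.amplitude_uM = abs(fitres.top - fitres.bottom)
        max_tc = float(sims[j].max()) if ref.shape[0] else 0.0
        rec.novelty_tc = max_tc
        rec.novel = max_tc < cfg.novelty_threshold
        rec.stage_reached = Stage.SIMULATED
    funnel["simulated"] = len(survivors)

    # rank by (probability desc, potency: smaller x50 first)
    def rank_key(m: str):
        r = records[m]
        x50 = r.x50_uM if r.x50_uM is not None else math.inf
        return (-(r.antagonist_probability or 0.0), x50, m)

    for rank, m in enumerate(sorted(survivors, key=rank_key), start=1):
        records[m].rank = rank
    return _finish(records, funnel, cfg, None)


def _finish(records: dict[str, CandidateRecord], funnel: dict[str, int],
            cfg: PipelineConfig, empty_stage: Optional[str]) -> PipelineResult:
    manifest = {"config_digest": cfg.digest(), "seed": cfg.seed,
                "stage_counts": dict(funnel)}
    return PipelineResult(records=list(records.values()), funnel=funnel,
                          manifest=manifest, empty_stage=empty_stage)


def records_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        d = asdict(r)
        d["stage_reached"] = r.stage_reached.name.lower()
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.sort_values(["rank", "molecule_id"],
                          na_position="last", ignore_index=True)


def render_report(result: PipelineResult) -> str:
    """Human-readable funnel summary plus the final ranked table."""
    lines = ["screening funnel"]
    for stage, count in result.funnel.items():
        lines.append(f"  {stage:<14s} {count:>6d}")
    if result.empty_stage:
        lines.append(f"  WARNING: funnel emptied at stage {result.empty_stage}")
    final = result.final
    lines.append("")
    lines.append(f"final candidates ({len(final)}):")
    lines.append("  rank  id            prob    pKd   x50_uM    novel")
    for r in final:
        x50 = f"{r.x50_uM:.3g}" if r.x50_uM is not None else "-"
        lines.append(f"  {r.rank:>4d}  {r.molecule_id:<12s} "
                     f"{r.antagonist_probability:.3f}  {r.predicted_pKd:5.2f} "
                     f" {x50:>8s}  {str(bool(r.novel)).lower()}")
    return "\n".join(lines)
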