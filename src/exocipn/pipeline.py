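"""End-to-end dual-track analysis: PSM table -> combined protein signature.

Order of operations: charge screening at load, precursor-tolerance filter,
one target-decoy FDR filtering pass over the pooled PSM table (all technical
replicates together), replicate merging of the accepted targets, then both
quantification tracks, per-track Mann-Whitney/BH differential testing at the
requested timepoint, peptide-to-protein roll-up, and the union/overlap
combination of the two selections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import diff_stats, psm_filter, quantify
from .digest import PeptideMapping
from .diff_stats import Signature, TrackResult


@dataclass
class DualTrackResult:
    """Everything the dual-track analysis produces for one timepoint."""

    timepoint: str
    q_threshold: float
    fdr_threshold: float | None
    n_accepted_psms: int
    protein: TrackResult
    peptide: TrackResult
    peptide_as_proteins: pd.DataFrame
    signature: Signature
    directions: dict[str, str]
    tally: tuple[int, int, int]


def run_dual_track(
    psms: pd.DataFrame,
    mapping: Sequence[PeptideMapping],
    sample_groups: Mapping[str, str],
    timepoint: str = "T0",
    q_threshold: float = 0.3,
    alpha: float = psm_filter.DEFAULT_PSM_ALPHA,
    max_ppm: float = psm_filter.DEFAULT_MAX_PPM,
    mode: str = "auto",
) -> DualTrackResult:
    psms = psm_filter.validate_psms(psms)
    psms = psm_filter.tolerance_filter(psms, max_ppm=max_ppm)
    accepted, threshold = psm_filter.filter_at_fdr(psms, alpha=alpha)
    merged = psm_filter.merge_replicates(accepted)

    protein_qm = quantify.build_protein_matrix(merged, mapping, sample_groups)
    peptide_qm = quantify.build_peptide_matrix(merged, mapping, sample_groups)

    protein_res = diff_stats.run_track(
        protein_qm, timepoint, q_threshold, mode=mode
    )
    peptide_res = diff_stats.run_track(
        peptide_qm, timepoint, q_threshold, mode=mode
    )
    rolled = quantify.roll_up_peptides(peptide_res.results, mapping)
    peptide_proteins = frozenset(
        rolled.loc[rolled["q_value"] < q_threshold, "feature"]
    )
    signature = diff_stats.combine_tracks(
        protein_res.selected,
        peptide_proteins,
        timepoint=timepoint,
        q_threshold=q_threshold,
    )
    directions = diff_stats.signature_directions(protein_res.results, rolled)
    tally = diff_stats.direction_tally(directions, signature)
    return DualTrackResult(
        timepoint=timepoint,
        q_threshold=q_threshold,
        fdr_threshold=threshold,
        n_accepted_psms=len(accepted),
        protein=protein_res,
        peptide=peptide_res,
        peptide_as_proteins=rolled,
        signature=signature,
        directions=directions,
        tally=tally,
    )
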