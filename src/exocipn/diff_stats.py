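"""Normalization, rank-based differential testing and dual-track signatures.

The differential machinery mirrors a small-cohort label-free workflow:

* per-sample library-size scaling (each column rescaled to the median column
  total) followed by ln(x + 1), giving comparable, variance-stabilised values;
* a two-sided Mann-Whitney U test per feature between the CIPN and stable
  groups — exact when the data are tie-free (at 8 vs 9 samples the exact null
  has C(17,8) = 24,310 arrangements and is cheap), otherwise the tie-corrected
  normal approximation with continuity correction;
* Benjamini-Hochberg adjustment per track and per timepoint, with selection
  at a strict q threshold (q < 0.2 for the core signature, q < 0.3 for the
  expanded one);
* combination of the protein-based and peptide-based selections by set union,
  with the overlap and per-direction tallies reported;
* a 2-D PCA of the selected features with a simple between/within separation
  index to visualise how well the two groups part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .quantify import QuantMatrix, TRACK_PROTEIN, TRACK_PEPTIDE

DIRECTION_G1 = "higher_in_group1"
DIRECTION_G2 = "higher_in_group2"
DIRECTION_TIED = "tied"

#: Largest combined group size for which the exact (tie-free) null is used.
EXACT_MAX_N = 30


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(qm: QuantMatrix) -> QuantMatrix:
    """Library-size scaling to the median column total, then ln(x + 1)."""
    totals = qm.values.sum(axis=0)
    zero_cols = list(totals.index[totals == 0])
    if zero_cols:
        raise ValueError(
            f"sample(s) with an all-zero column cannot be normalized: "
            f"{zero_cols[:5]}"
        )
    target = float(np.median(totals.to_numpy(dtype=float)))
    scaled = qm.values * (target / totals)
    values = np.log1p(scaled)
    return QuantMatrix(
        track=qm.track, values=values, samples=qm.samples, normalized=True
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for ``a``, p).

    ``mode='auto'`` uses the exact null distribution whenever the pooled data
    are tie-free and the combined size is modest (<= 30), and otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  Fully degenerate input (all values identical in both
    groups) is flagged as p = 1.0 with the central U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p = 1")
        return a.size * b.size / 2.0, 1.0
    if mode == "auto":
        use_exact = not _has_ties(pooled) and pooled.size <= EXACT_MAX_N
    else:
        use_exact = mode == "exact"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _mann_whitney_rows(
    A: np.ndarray, B: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney over a features x samples split, vectorised."""
    n_rows = A.shape[0]
    U = np.empty(n_rows)
    p = np.empty(n_rows)
    pooled = np.concatenate([A, B], axis=1)
    degenerate = np.all(pooled == pooled[:, :1], axis=1)
    sorted_pool = np.sort(pooled, axis=1)
    tied = (np.diff(sorted_pool, axis=1) == 0).any(axis=1)
    if mode == "auto":
        exact_rows = ~tied & ~degenerate & (pooled.shape[1] <= EXACT_MAX_N)
    elif mode == "exact":
        exact_rows = ~degenerate
    else:
        exact_rows = np.zeros(n_rows, dtype=bool)
    asym_rows = ~exact_rows & ~degenerate

    for mask, method in ((exact_rows, "exact"), (asym_rows, "asymptotic")):
        if mask.any():
            res = stats.mannwhitneyu(
                A[mask], B[mask], alternative="two-sided",
                method=method, axis=1,
            )
            U[mask] = res.statistic
            p[mask] = np.minimum(res.pvalue, 1.0)
    if degenerate.any():
        U[degenerate] = A.shape[1] * B.shape[1] / 2.0
        p[degenerate] = 1.0
    return U, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Per-track differential analysis
# ---------------------------------------------------------------------------


@dataclass
class TrackResult:
    """Per-feature test outcomes for one track at one timepoint."""

    track: str
    timepoint: str
    results: pd.DataFrame  # feature, U, p_value, q_value, direction, selected
    q_threshold: float

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(
            self.results.loc[self.results["selected"], "feature"]
        )

    def selected_at(self, q_threshold: float) -> frozenset[str]:
        return frozenset(
            self.results.loc[
                self.results["q_value"] < q_threshold, "feature"
            ]
        )


def run_track(
    qm: QuantMatrix,
    timepoint: str,
    q_threshold: float,
    mode: str = "auto",
) -> TrackResult:
    """Differential test of every feature between the two groups at one visit.

    Normalizes (unless the matrix is already normalized), tests each feature
    with the Mann-Whitney U, adjusts across all features of this
    track/timepoint with Benjamini-Hochberg, and selects features with
    q strictly below ``q_threshold``.  Direction is the comparison of group
    medians on the normalized values (equal medians count as tied).
    """
    sub = qm.at_timepoint(timepoint)
    groups = sorted(sub.samples["group"].unique())
    if len(groups) != 2:
        raise ValueError(
            f"expected exactly two groups at {timepoint!r}, got {groups}"
        )
    g1, g2 = groups
    mask1 = (sub.samples["group"] == g1).to_numpy()
    mask2 = (sub.samples["group"] == g2).to_numpy()
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 samples at {timepoint!r} "
            f"(got {int(mask1.sum())} vs {int(mask2.sum())})"
        )
    norm = sub if sub.normalized else normalize(sub)
    X = norm.values.to_numpy(dtype=float)
    A, B = X[:, mask1], X[:, mask2]

    U, p = _mann_whitney_rows(A, B, mode)
    q = bh_adjust(p)
    med1 = np.median(A, axis=1)
    med2 = np.median(B, axis=1)
    direction = np.where(
        med1 > med2,
        DIRECTION_G1,
        np.where(med2 > med1, DIRECTION_G2, DIRECTION_TIED),
    )
    results = pd.DataFrame(
        {
            "feature": list(norm.values.index),
            "track": qm.track,
            "timepoint": timepoint,
            "u_statistic": U,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "selected_q02": q < 0.2,
            "selected_q03": q < 0.3,
            "selected": q < q_threshold,
        }
    )
    return TrackResult(
        track=qm.track,
        timepoint=timepoint,
        results=results,
        q_threshold=q_threshold,
    )


# ---------------------------------------------------------------------------
# Dual-track combination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Signature:
    """Selected protein sets from the two tracks and their combination."""

    timepoint: str
    q_threshold: float
    protein_track: frozenset[str]
    peptide_track: frozenset[str]

    @property
    def overlap(self) -> frozenset[str]:
        return self.protein_track & self.peptide_track

    @property
    def combined(self) -> frozenset[str]:
        return self.protein_track | self.peptide_track

    def sizes(self) -> dict[str, int]:
        return {
            "protein_track": len(self.protein_track),
            "peptide_track": len(self.peptide_track),
            "overlap": len(self.overlap),
            "combined": len(self.combined),
        }


def combine_tracks(
    protein_sel: Iterable[str],
    peptide_sel_as_proteins: Iterable[str],
    timepoint: str = "T0",
    q_threshold: float = 0.3,
) -> Signature:
    """Union/intersection of the two track selections (protein accessions)."""
    return Signature(
        timepoint=timepoint,
        q_threshold=q_threshold,
        protein_track=frozenset(protein_sel),
        peptide_track=frozenset(peptide_sel_as_proteins),
    )


def direction_tally(
    directions: Mapping[str, str], signature: Signature
) -> tuple[int, int, int]:
    """Counts of combined-signature members by direction of change.

    Returns (higher in group 1, higher in group 2, tied); the counts sum to
    the combined signature size.  Every member must have a direction.
    """
    counts = {DIRECTION_G1: 0, DIRECTION_G2: 0, DIRECTION_TIED: 0}
    for member in sorted(signature.combined):
        if member not in directions:
            raise ValueError(f"no differential result for member {member!r}")
        d = directions[member]
        if d not in counts:
            raise ValueError(f"unknown direction {d!r} for {member!r}")
        counts[d] += 1
    return counts[DIRECTION_G1], counts[DIRECTION_G2], counts[DIRECTION_TIED]


def signature_directions(
    protein_results: pd.DataFrame,
    peptide_protein_results: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Per-protein direction map, preferring the protein track.

    Proteins reported only by the peptide track fall back to the direction of
    their best (minimum-q) unique peptide.
    """
    directions = dict(
        zip(protein_results["feature"], protein_results["direction"])
    )
    if peptide_protein_results is not None:
        for feat, d in zip(
            peptide_protein_results["feature"],
            peptide_protein_results["direction"],
        ):
            directions.setdefault(feat, d)
    return directions


# ---------------------------------------------------------------------------
# PCA separation
# ---------------------------------------------------------------------------


def pca_separation(
    values: pd.DataFrame, labels: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Project samples onto the top 2 PCs and score group separation.

    ``values`` is features x samples (typically normalized and restricted to
    a signature).  Features are centered; values are not variance-scaled.
    The separation index is the distance between the two group centroids in
    the 2-D score space divided by the mean distance of samples to their own
    group centroid.  Identical samples (zero variance) are a degenerate
    input; rank-1 data fall back to a 1-D projection with a warning.
    """
    if values.shape[1] < 3:
        raise ValueError("PCA separation requires at least 3 samples")
    if values.shape[0] < 2:
        raise ValueError("PCA separation requires at least 2 features")
    missing = [c for c in values.columns if c not in labels]
    if missing:
        raise ValueError(f"no group label for sample(s): {missing[:5]}")
    X = values.to_numpy(dtype=float).T  # samples x features
    centered = X - X.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("identical samples: separation is undefined")
    rank = np.linalg.matrix_rank(centered)
    n_comp = min(2, rank, X.shape[0] - 1)
    if n_comp < 2:
        warnings.warn("data rank < 2; falling back to a 1-D projection")
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    if n_comp < 2:
        scores = np.column_stack([scores, np.zeros(scores.shape[0])])
    score_df = pd.DataFrame(
        scores, index=values.columns, columns=["pc1", "pc2"]
    )
    groups = pd.Series({c: labels[c] for c in values.columns})
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {names}")
    cent = {g: scores[(groups == g).to_numpy()].mean(axis=0) for g in names}
    between = float(np.linalg.norm(cent[names[0]] - cent[names[1]]))
    within = float(
        np.mean(
            [
                np.linalg.norm(scores[i] - cent[groups.iloc[i]])
                for i in range(len(groups))
            ]
        )
    )
    if within == 0:
        return score_df, np.inf
    return score_df, between / within


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(str(path), sep="\t", index=False)


def write_signature_report(signature: Signature, txt_path, csv_path) -> None:
    sizes = signature.sizes()
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(
            f"Signature at {signature.timepoint} "
            f"(q < {signature.q_threshold})\n"
        )
        for key, n in sizes.items():
            fh.write(f"{key}: {n}\n")
    rows = []
    for member in sorted(signature.combined):
        rows.append(
            {
                "protein": member,
                "in_protein_track": member in signature.protein_track,
                "in_peptide_track": member in signature.peptide_track,
                "in_overlap": member in signature.overlap,
            }
        )
    pd.DataFrame(rows).to_csv(str(csv_path), index=False)
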