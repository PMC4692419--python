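"""Synthetic cohorts, proteomes and PSM tables with ground-truth bookkeeping.

The generator emulates the statistical structure of a small dual-track serum
exosome study: two patient groups (8 with CIPN, 9 stable), serum drawn at
baseline (T0) and 12 months (T12), three technical LC-MS/MS replicates per
draw, ~800 detectable proteins, and a planted minority of differential
proteins (default 12 at a 4-fold effect, most elevated in the stable group).

Per sample x replicate, each protein receives a negative-binomial PSM count
around a log-normal baseline abundance; PSMs are distributed over the
protein's fully tryptic peptides, carry log-normal peak areas scaled to
abundance, and Gaussian discriminant scores.  A configurable fraction of
target PSMs are "incorrect" (assigned to a random wrong protein, scored from
the low distribution), and decoy PSMs are drawn from the same generating law
as the incorrect targets, so the decoy-estimated FDR downstream is
calibrated by construction.

All randomness flows from the single config seed; equal configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    FactNtxAssessment,
    GroupLabel,
    PatientRecord,
    Timepoint,
    classify_cipn,
    write_cohort_csv,
)
from .digest import ProteinEntry, tryptic_digest, write_fasta
from .psm_filter import PSM_COLUMNS, write_psm_table
from .quantify import sample_key

TIMEPOINTS = ("T0", "T12")

_CHARGE_STATES = np.array([2, 3, 4, 5, 6])
_CHARGE_PROBS = np.array([0.60, 0.30, 0.07, 0.02, 0.01])

# Residue pools for proteome construction: peptide cores avoid K/R (no
# internal cleavage sites) and never start with P (no suppressed cleavage).
_CORE_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))
_FIRST_RESIDUES = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass
class SimulationConfig:
    """Knobs of the study emulation; defaults mirror the cohort's design."""

    seed: int = 0
    n_group1: int = 8
    n_group2: int = 9
    n_proteins: int = 800
    n_differential: int = 12
    effect_log_fold: float = math.log(4.0)
    #: fraction of planted effects elevated in the stable group (group 2).
    fraction_higher_group2: float = 32 / 37
    shared_peptide_fraction: float = 0.10
    #: negative-binomial dispersion: var = mu + dispersion * mu^2.
    count_dispersion: float = 0.10
    area_cv: float = 0.30
    n_replicates: int = 3
    #: separation (in SD units) between correct and incorrect/decoy scores.
    decoy_score_shift: float = 3.5
    incorrect_target_fraction: float = 0.10
    #: expected replicate-merged PSM count per protein per sample draw.
    mean_psms_per_protein: float = 10.0
    #: log-normal spread of per-protein baseline abundances.
    abundance_sigma: float = 0.8
    #: CV of the per-run depth factor (injection/loading variability) — the
    #: nuisance that library-size normalization exists to remove.
    depth_cv: float = 0.20

    def __post_init__(self) -> None:
        if self.n_differential > self.n_proteins:
            raise ValueError("n_differential must be <= n_proteins")
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if not 0 <= self.shared_peptide_fraction < 1:
            raise ValueError("shared_peptide_fraction must be in [0, 1)")
        if not 0 <= self.incorrect_target_fraction < 1:
            raise ValueError("incorrect_target_fraction must be in [0, 1)")
        if not 0 <= self.fraction_higher_group2 <= 1:
            raise ValueError("fraction_higher_group2 must be in [0, 1]")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.area_cv <= 0:
            raise ValueError("area_cv must be > 0")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")
        if self.decoy_score_shift <= 0:
            raise ValueError("decoy_score_shift must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_group1 < 0 or self.n_group2 < 0:
            raise ValueError("group sizes must be >= 0")


@dataclass
class GroundTruth:
    """Generation-time bookkeeping for validating every pipeline stage."""

    sample_groups: dict[str, str]
    #: accession -> {"direction": ..., "log_fold": ...} for planted effects.
    differential: dict[str, dict]
    #: proteins x sample keys: replicate-merged target-PSM counts by the
    #: protein of the *assigned* peptide (incorrect assignments included).
    psm_allocation: pd.DataFrame | None = None
    #: per-row correctness flag aligned with the generated PSM table
    #: (decoy rows are False).
    psm_correct: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "sample_groups": self.sample_groups,
            "differential": self.differential,
            "psm_allocation": (
                None
                if self.psm_allocation is None
                else {
                    "index": list(self.psm_allocation.index),
                    "columns": list(self.psm_allocation.columns),
                    "values": self.psm_allocation.to_numpy().tolist(),
                }
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        alloc = payload.get("psm_allocation")
        return cls(
            sample_groups=payload["sample_groups"],
            differential=payload["differential"],
            psm_allocation=(
                None
                if alloc is None
                else pd.DataFrame(
                    np.asarray(alloc["values"], dtype=np.int64),
                    index=alloc["index"],
                    columns=alloc["columns"],
                )
            ),
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Per-group demographic category weights, taken from the two study arms
# (CIPN n=8 / stable n=9).
_G1, _G2 = GroupLabel.GROUP1_CIPN.value, GroupLabel.GROUP2_STABLE.value

_DEMOGRAPHIC_WEIGHTS: dict[str, dict[str, list[tuple[str, int]]]] = {
    "race": {
        _G1: [("White", 6), ("Black or African American", 2)],
        _G2: [("White", 3), ("Black or African American", 6)],
    },
    "ethnicity": {
        _G1: [("Non-Hispanic", 5), ("Hispanic", 2), ("Other", 1)],
        _G2: [("Non-Hispanic", 2), ("Hispanic", 5), ("Other", 2)],
    },
    "smoking": {
        _G1: [("Never smoked", 3), ("Quit", 5)],
        _G2: [("Never smoked", 2), ("Quit", 7)],
    },
    "alcohol_per_week": {
        _G1: [("None", 4), ("<1/week", 2), ("1-6/week", 1), ("Unknown", 1)],
        _G2: [("None", 3), ("<1/week", 2), ("1-6/week", 3), ("Unknown", 1)],
    },
    "menopause": {
        _G1: [("Pre-menopausal", 6), ("Post-menopausal", 2)],
        _G2: [("Pre-menopausal", 3), ("Post-menopausal", 6)],
    },
    "stage": {
        _G1: [("1", 0), ("2", 6), ("3", 2)],
        _G2: [("1", 3), ("2", 4), ("3", 2)],
    },
    "er_status": {
        _G1: [("Positive", 6), ("Negative", 2)],
        _G2: [("Positive", 5), ("Negative", 4)],
    },
    "pr_status": {
        _G1: [("Positive", 5), ("Negative", 3)],
        _G2: [("Positive", 4), ("Negative", 5)],
    },
    "her2_status": {
        _G1: [("Positive", 1), ("Negative", 7)],
        _G2: [("Positive", 1), ("Negative", 8)],
    },
    "taxane_regimen": {
        _G1: [("Tx4 q 2 wks", 5), ("Tx6 q 2 wks", 1), ("Tx12 q wk", 2)],
        _G2: [("Tx4 q 2 wks", 9), ("Tx6 q 2 wks", 0), ("Tx12 q wk", 0)],
    },
    "prior_chemo": {
        _G1: [("None", 1), ("AC x 4 q 2 wks", 6), ("AC x 6 q 3 wks", 1)],
        _G2: [("None", 2), ("AC x 4 q 2 wks", 7), ("AC x 6 q 3 wks", 0)],
    },
}

_AGE_PARAMS = {_G1: (48.5, 13.75), _G2: (50.3, 11.6)}
_BMI_PARAMS = {_G1: (29.38, 10.16), _G2: (28.22, 2.99)}

_MAX_RESAMPLE = 1000


def _sample_category(rng, weights: list[tuple[str, int]]) -> str:
    levels = [w[0] for w in weights]
    counts = np.array([w[1] for w in weights], dtype=float)
    return levels[rng.choice(len(levels), p=counts / counts.sum())]


def _trajectory(rng, group: str) -> list[tuple[Timepoint, int]] | None:
    """One baseline + three follow-up scores consistent with ``group``."""
    baseline = int(rng.integers(30, 45))
    if group == _G1:
        worst = rng.uniform(0.20, 0.60)
        worst_at = rng.integers(0, 3)
        worsenings = [
            worst if j == worst_at else rng.uniform(0.0, worst)
            for j in range(3)
        ]
    else:
        worsenings = [rng.uniform(-0.05, 0.15) for _ in range(3)]
    scores = [int(round(baseline * (1 - w))) for w in worsenings]
    if any(s < 0 or s > 44 for s in scores):
        return None
    followups = [
        (tp, s)
        for tp, s in zip(
            (Timepoint.COMPLETION, Timepoint.MONTH6, Timepoint.MONTH12), scores
        )
    ]
    return [(Timepoint.BASELINE, baseline), *followups]


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], dict[str, str]]:
    """Patients with planted group labels and consistent score trajectories.

    Group-1 patients receive a worst-case fractional worsening drawn from
    [0.20, 0.60]; group-2 patients from [-0.05, 0.15] at every visit.
    Integer rounding can push a drawn trajectory across the 20% boundary or
    outside the 0-44 score range; such draws are resampled (never clamped)
    until the classification rule reproduces the planted label.
    """
    rng = _rng(config, 1)
    patients: list[PatientRecord] = []
    labels: dict[str, str] = {}
    plan = [(_G1, config.n_group1), (_G2, config.n_group2)]
    idx = 0
    for group, n in plan:
        for _ in range(n):
            idx += 1
            pid = f"P{idx:02d}"
            for attempt in range(_MAX_RESAMPLE):
                traj = _trajectory(rng, group)
                if traj is None:
                    continue
                assessments = [
                    FactNtxAssessment(pid, tp, score) for tp, score in traj
                ]
                mean, sd = _AGE_PARAMS[group]
                age = float(rng.normal(mean, sd))
                while age < 18 or age > 90:
                    age = float(rng.normal(mean, sd))
                mean, sd = _BMI_PARAMS[group]
                bmi = float(rng.normal(mean, sd))
                while bmi < 15 or bmi > 60:
                    bmi = float(rng.normal(mean, sd))
                patient = PatientRecord(
                    patient_id=pid,
                    age_years=round(age, 1),
                    bmi=round(bmi, 2),
                    assessments=assessments,
                    **{
                        var: _sample_category(rng, _DEMOGRAPHIC_WEIGHTS[var][group])
                        for var in _DEMOGRAPHIC_WEIGHTS
                    },
                )
                if classify_cipn(patient).value == group:
                    break
            else:  # pragma: no cover - bounded-resample guard
                raise RuntimeError(f"could not realise a {group} trajectory")
            patients.append(patient)
            labels[pid] = group
    return patients, labels


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------


def generate_proteome(config: SimulationConfig) -> list[ProteinEntry]:
    """Random tryptic-friendly proteins, with optional planted shared peptides.

    Each protein is a concatenation of segments (a 6-14 residue core free of
    K/R and not starting with P, terminated by K or R), so every segment is a
    clean fully tryptic peptide of length 7-15 and each protein yields at
    least two of them.  Protein lengths land in roughly [120, 615].  A
    ``shared_peptide_fraction`` of proteins then has one internal segment
    replaced by a segment copied from another protein, creating non-unique
    peptides.
    """
    rng = _rng(config, 2)
    n = config.n_proteins
    segmented: list[list[str]] = []
    for _ in range(n):
        target_len = int(rng.integers(120, 601))
        max_seg = target_len // 7 + 2
        lens = rng.integers(6, 15, size=max_seg)
        terminals = rng.choice(np.array(["K", "R"]), size=max_seg)
        cores = rng.integers(0, len(_CORE_RESIDUES), size=int(lens.sum()))
        firsts = rng.integers(0, len(_FIRST_RESIDUES), size=max_seg)
        segments: list[str] = []
        total = 0
        offset = 0
        for j in range(max_seg):
            core_len = int(lens[j])
            body = "".join(_CORE_RESIDUES[cores[offset + 1 : offset + core_len]])
            seg = _FIRST_RESIDUES[firsts[j]] + body + terminals[j]
            offset += core_len
            segments.append(seg)
            total += len(seg)
            if total >= target_len:
                break
        segmented.append(segments)

    n_shared = int(round(config.shared_peptide_fraction * n))
    if n_shared:
        recipients = rng.choice(n, size=n_shared, replace=False)
        for r in recipients:
            donor = int(rng.integers(0, n - 1))
            if donor >= r:
                donor += 1
            donor_segs = segmented[donor]
            seg = donor_segs[int(rng.integers(0, len(donor_segs)))]
            pos = int(rng.integers(1, len(segmented[r]) - 1))
            segmented[r][pos] = seg

    width = len(str(n))
    return [
        ProteinEntry(
            accession=f"PROT{i + 1:0{width}d}",
            sequence="".join(segs),
            description="synthetic serum exosome protein",
        )
        for i, segs in enumerate(segmented)
    ]


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------


def simulate_psms(
    config: SimulationConfig,
    proteome: list[ProteinEntry],
    sample_groups: dict[str, str],
) -> tuple[pd.DataFrame, GroundTruth]:
    """PSM table over all samples, timepoints and replicates, plus truth.

    Planted effects multiply the abundance of each differential protein by
    exp(effect_log_fold) in its elevated group at both timepoints.
    Differential proteins are drawn from the upper half of the baseline
    abundance distribution (a marker invisible at the run depth would not be
    detectable by any method).
    """
    rng = _rng(config, 3)
    P = len(proteome)
    peptides_per_protein = [
        tryptic_digest(e.sequence, min_length=7, missed_cleavages=0)
        for e in proteome
    ]
    n_peps = np.array([len(p) for p in peptides_per_protein])
    if (n_peps < 1).any():
        raise ValueError("every protein must yield at least one peptide")
    pep_offsets = np.concatenate([[0], np.cumsum(n_peps)[:-1]])
    all_peps = np.array(
        [p for peps in peptides_per_protein for p in peps], dtype=object
    )
    accessions = np.array([e.accession for e in proteome], dtype=object)

    mu_base = config.mean_psms_per_protein
    sigma = config.abundance_sigma
    abundance = rng.lognormal(
        mean=math.log(mu_base) - sigma**2 / 2, sigma=sigma, size=P
    )

    # Planted differential effects.
    differential: dict[str, dict] = {}
    fold_g1 = np.ones(P)
    fold_g2 = np.ones(P)
    if config.effect_log_fold != 0 and config.n_differential > 0:
        eligible = np.flatnonzero(abundance >= np.median(abundance))
        chosen = rng.choice(eligible, size=config.n_differential, replace=False)
        chosen = rng.permutation(chosen)
        n_up_g2 = int(round(config.fraction_higher_group2 * len(chosen)))
        factor = math.exp(config.effect_log_fold)
        for k, i in enumerate(chosen):
            if k < n_up_g2:
                fold_g2[i] = factor
                direction = "higher_in_group2"
            else:
                fold_g1[i] = factor
                direction = "higher_in_group1"
            differential[str(accessions[i])] = {
                "direction": direction,
                "log_fold": config.effect_log_fold,
            }

    samples = sorted(sample_groups)
    runs: list[tuple[str, str, int]] = [
        (s, tp, r)
        for s in samples
        for tp in TIMEPOINTS
        for r in range(1, config.n_replicates + 1)
    ]
    n_runs = len(runs)
    group_is_g1 = np.array(
        [sample_groups[s] == _G1 for s, _, _ in runs]
    )
    fold = np.where(group_is_g1[:, None], fold_g1[None, :], fold_g2[None, :])
    if config.depth_cv > 0:
        s_depth = math.sqrt(math.log(1 + config.depth_cv**2))
        depth = rng.lognormal(-(s_depth**2) / 2, s_depth, size=n_runs)
    else:
        depth = np.ones(n_runs)
    mu = abundance[None, :] * fold * depth[:, None] / config.n_replicates

    r_nb = 1.0 / config.count_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))

    run_idx = np.repeat(np.arange(n_runs), P)
    prot_idx = np.tile(np.arange(P), n_runs)
    flat = counts.ravel()
    psm_run = np.repeat(run_idx, flat)
    psm_prot = np.repeat(prot_idx, flat)
    n_psm = int(flat.sum())

    # Incorrect targets: reassigned to a random protein, scored low.
    incorrect = rng.random(n_psm) < config.incorrect_target_fraction
    n_inc = int(incorrect.sum())
    psm_prot = psm_prot.copy()
    psm_prot[incorrect] = rng.integers(0, P, size=n_inc)

    pep_local = np.floor(rng.random(n_psm) * n_peps[psm_prot]).astype(np.int64)
    pep_global = pep_offsets[psm_prot] + pep_local
    peptides = all_peps[pep_global]

    scores = np.where(
        incorrect,
        rng.normal(0.0, 1.0, size=n_psm),
        rng.normal(config.decoy_score_shift, 1.0, size=n_psm),
    )
    sigma_area = math.sqrt(math.log(1 + config.area_cv**2))
    run_fold = fold[psm_run, psm_prot]
    base = abundance[psm_prot] * run_fold * depth[psm_run]
    areas = 1e5 * base * rng.lognormal(
        mean=-(sigma_area**2) / 2, sigma=sigma_area, size=n_psm
    )
    ppm = np.where(
        incorrect,
        rng.uniform(-12, 12, size=n_psm),
        rng.normal(0.0, 2.5, size=n_psm),
    )
    charges = rng.choice(_CHARGE_STATES, p=_CHARGE_PROBS, size=n_psm)

    # Decoys: one block per run, count drawn from the same law as the
    # incorrect-target count (Binomial over the run's PSM total).
    run_totals = counts.sum(axis=1)
    n_dec_per_run = rng.binomial(run_totals, config.incorrect_target_fraction)
    n_dec = int(n_dec_per_run.sum())
    dec_run = np.repeat(np.arange(n_runs), n_dec_per_run)
    dec_prot = rng.integers(0, P, size=n_dec)
    dec_local = np.floor(rng.random(n_dec) * n_peps[dec_prot]).astype(np.int64)
    dec_peps = np.array(
        [p[::-1] for p in all_peps[pep_offsets[dec_prot] + dec_local]],
        dtype=object,
    )
    dec_scores = rng.normal(0.0, 1.0, size=n_dec)
    dec_areas = 1e5 * abundance[dec_prot] * rng.lognormal(
        mean=-(sigma_area**2) / 2, sigma=sigma_area, size=n_dec
    )
    dec_ppm = rng.uniform(-12, 12, size=n_dec)
    dec_charges = rng.choice(_CHARGE_STATES, p=_CHARGE_PROBS, size=n_dec)

    all_run = np.concatenate([psm_run, dec_run])
    order = np.argsort(all_run, kind="stable")
    sample_arr = np.array([r[0] for r in runs], dtype=object)
    tp_arr = np.array([r[1] for r in runs], dtype=object)
    rep_arr = np.array([r[2] for r in runs])

    col_run = all_run[order]
    within = _within_run_counter(col_run, n_runs)
    run_prefix = np.array(
        [f"{s}_{tp}_r{r}" for s, tp, r in runs], dtype=object
    )
    spectrum_ids = (
        pd.Series(run_prefix[col_run]) + "_" + pd.Series(within).astype(str)
    )

    def _cat(a, b):
        return np.concatenate([a, b])[order]

    psms = pd.DataFrame(
        {
            "spectrum_id": spectrum_ids.to_numpy(),
            "sample_id": sample_arr[col_run],
            "replicate_id": rep_arr[col_run],
            "timepoint": tp_arr[col_run],
            "peptide": _cat(peptides, dec_peps),
            "charge": _cat(charges, dec_charges).astype(np.int64),
            "score": _cat(scores, dec_scores),
            "is_decoy": _cat(
                np.zeros(n_psm, dtype=np.int64), np.ones(n_dec, dtype=np.int64)
            ),
            "peak_area": _cat(areas, dec_areas),
            "precursor_error_ppm": _cat(ppm, dec_ppm),
        },
        columns=list(PSM_COLUMNS),
    )

    # Replicate-merged target-PSM allocation per assigned protein and sample.
    alloc_keys = [
        sample_key(s, tp) for s in samples for tp in TIMEPOINTS
    ]
    key_of_run = np.array(
        [alloc_keys.index(sample_key(s, tp)) for s, tp, _ in runs]
    )
    alloc = np.zeros((P, len(alloc_keys)), dtype=np.int64)
    np.add.at(alloc, (psm_prot, key_of_run[psm_run]), 1)
    allocation = pd.DataFrame(
        alloc, index=list(accessions), columns=alloc_keys
    )

    correct_flags = np.concatenate(
        [~incorrect, np.zeros(n_dec, dtype=bool)]
    )[order]
    truth = GroundTruth(
        sample_groups=dict(sample_groups),
        differential=differential,
        psm_allocation=allocation,
        psm_correct=correct_flags,
    )
    return psms, truth


def _within_run_counter(sorted_run_ids: np.ndarray, n_runs: int) -> np.ndarray:
    """0-based position of each row within its (sorted, contiguous) run."""
    n = sorted_run_ids.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    counts = np.bincount(sorted_run_ids, minlength=n_runs)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.arange(n) - np.repeat(starts, counts)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    patients: list[PatientRecord]
    labels: dict[str, str]
    proteome: list[ProteinEntry]
    psms: pd.DataFrame
    truth: GroundTruth


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Cohort -> proteome -> PSM table, optionally written to ``out_dir``.

    Emits the exact dialects the analysis modules consume: cohort.csv,
    proteome.fasta, psms.tsv, and truth.json beside them.
    """
    patients, labels = generate_cohort(config)
    proteome = generate_proteome(config)
    psms, truth = simulate_psms(config, proteome, labels)
    dataset = SimulatedDataset(
        config=config,
        patients=patients,
        labels=labels,
        proteome=proteome,
        psms=psms,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(patients, out / "cohort.csv")
        write_fasta(proteome, out / "proteome.fasta")
        write_psm_table(psms, out / "psms.tsv")
        truth.to_json(out / "truth.json")
        with open(out / "config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return dataset
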