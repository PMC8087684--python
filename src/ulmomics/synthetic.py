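"""Synthetic paired-omics cohorts and 2SC PSM tables with known planted structure.

The generator emulates the statistical skeleton of a two-cohort paired
transcript/protein tumor study: per-sample cross-ome Spearman correlation
with a different target per cohort (planted through the Gaussian-copula
conversion r = 2 sin(pi * rho_S / 6)), per-gene log2 fold-change effects,
technical replicates with a target correlation, and succinated-peptide PSM
tables with a planted cohort shift and missingness.  Every draw derives from
one seeded generator so identical configs reproduce bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CohortDesign, ExpressionMatrix, PairedOmics, PsmTable

AMINO_ACIDS = "ADEFGHIKLMNPQRSTVWY"  # no C; cysteines are placed explicitly
SUCCINATION_DELTA_DA = 116.0109


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Planted generator parameters, returned alongside every synthetic dataset.

    ``cohort_rho`` maps cohort label -> target per-sample Spearman correlation
    between the protein and transcript profiles of each sample in that
    cohort.  ``rho_spread`` is the within-cohort SD of per-sample targets.
    ``protein_log2fc``/``transcript_log2fc`` map gene -> planted cohort-A
    effect.  ``psm_shift`` is the cohort-A log2 shift of succinated peptides
    and ``psm_noise_sd`` the per-measurement noise SD.
    """

    cohort_rho: dict = field(default_factory=dict)
    protein_log2fc: dict = field(default_factory=dict)
    transcript_log2fc: dict = field(default_factory=dict)
    psm_shift: float = 0.0
    psm_noise_sd: float = 0.5
    replicate_rho: float = 0.83
    rho_spread: float = 0.05
    case_cohort: str | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def spearman_to_pearson(rho_s: float) -> float:
    """Latent bivariate-normal Pearson correlation with population Spearman rho_s.

    Uses the exact Gaussian-copula relation r = 2 sin(pi * rho_s / 6); valid
    on the open interval (-1, 1).  Targets within 1e-6 of +/-1 are rejected:
    the implied noise weight sqrt(1 - r^2) underflows there and the planted
    correlation degenerates to an exact copy.
    """
    if abs(rho_s) > 1 - 1e-6:
        raise SyntheticConfigError(f"target Spearman must lie inside (-1, 1), got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def default_design(n_a: int = 16, n_b: int = 12, cohort_a: str = "HLRCC", cohort_b: str = "NS") -> CohortDesign:
    """A two-cohort design shaped like the motivating study (16 vs 12 tumors)."""
    rows = [{"sample_id": f"{cohort_a}_{i + 1:02d}", "cohort": cohort_a, "patient_id": f"P{i + 1:02d}"} for i in range(n_a)]
    rows += [{"sample_id": f"{cohort_b}_{i + 1:02d}", "cohort": cohort_b, "patient_id": f"P{n_a + i + 1:02d}"} for i in range(n_b)]
    return CohortDesign(pd.DataFrame(rows).set_index("sample_id"))


def _case_cohort(config: SyntheticTruth, design: CohortDesign) -> str:
    if config.case_cohort is not None:
        return config.case_cohort
    return design.cohort_pair()[0]


def generate_paired_cohort(
    config: SyntheticTruth,
    n_genes: int,
    design: CohortDesign,
    rng: np.random.Generator | None = None,
) -> tuple[PairedOmics, CohortDesign, SyntheticTruth]:
    """Draw a paired transcript/protein cohort with planted per-sample correlation.

    Per sample s in cohort c: transcript profile ~ iid N(0, 1) across genes;
    protein profile = r_s * transcript + sqrt(1 - r_s^2) * noise, where r_s is
    the Pearson conversion of a per-sample Spearman target drawn
    N(cohort_rho[c], rho_spread).  Planted per-gene log2FC values (per layer)
    are then added to case-cohort samples.  Named genes in the log2FC maps are
    appended after the G0001... background genes.
    """
    if n_genes < 10:
        raise SyntheticConfigError("need n_genes >= 10")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cohorts = design.cohort_levels()
    for c in cohorts:
        if c not in config.cohort_rho:
            raise SyntheticConfigError(f"cohort {c!r} missing from config.cohort_rho")
    named = sorted(set(config.protein_log2fc) | set(config.transcript_log2fc))
    background = [f"G{i + 1:04d}" for i in range(n_genes - len(named))]
    genes = background + named
    samples = design.sample_ids
    case = _case_cohort(config, design)

    transcript = np.empty((len(genes), len(samples)))
    protein = np.empty_like(transcript)
    for j, s in enumerate(samples):
        c = design.table.loc[s, "cohort"]
        rho_c = config.cohort_rho[c]
        if abs(rho_c) == 1.0:  # deterministic copy: zero noise weight, no jitter
            r = math.copysign(1.0, rho_c)
        else:
            rho_target = float(np.clip(rng.normal(rho_c, config.rho_spread), -0.999, 0.999))
            r = spearman_to_pearson(rho_target)
        z = rng.standard_normal(len(genes))
        eps = rng.standard_normal(len(genes))
        transcript[:, j] = z
        protein[:, j] = r * z + math.sqrt(1.0 - r * r) * eps
    for g, fc in config.protein_log2fc.items():
        i = genes.index(g)
        for j, s in enumerate(samples):
            if design.table.loc[s, "cohort"] == case:
                protein[i, j] += fc
    for g, fc in config.transcript_log2fc.items():
        i = genes.index(g)
        for j, s in enumerate(samples):
            if design.table.loc[s, "cohort"] == case:
                transcript[i, j] += fc

    paired = PairedOmics(
        protein=ExpressionMatrix(pd.DataFrame(protein, index=genes, columns=samples), "protein"),
        transcript=ExpressionMatrix(pd.DataFrame(transcript, index=genes, columns=samples), "transcript"),
    )
    return paired, design, config


def add_technical_replicates(
    paired_or_matrix: ExpressionMatrix,
    design: CohortDesign,
    patients: list[str],
    config: SyntheticTruth,
    rng: np.random.Generator | None = None,
    target_rho: float | None = None,
) -> tuple[ExpressionMatrix, CohortDesign]:
    """Append a second technical replicate for the given patients.

    The replicate column correlates with replicate #1 at the planted target
    (Gaussian-copula conversion again); the design gains replicate_index 1/2.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    rho = config.replicate_rho if target_rho is None else target_rho
    r = spearman_to_pearson(rho)
    data = paired_or_matrix.data.copy()
    table = design.table.copy()
    if "replicate_index" not in table.columns:
        table["replicate_index"] = 1
    for patient in patients:
        first = table.index[table["patient_id"] == patient]
        if len(first) == 0:
            raise SyntheticConfigError(f"unknown patient {patient!r}")
        s1 = first[0]
        base = data[s1].to_numpy()
        sd = float(np.std(base)) or 1.0
        rep = r * (base - base.mean()) / sd + math.sqrt(1 - r * r) * rng.standard_normal(len(base))
        rep = rep * sd + base.mean()
        s2 = f"{s1}_rep2"
        data[s2] = rep
        table.loc[s2] = table.loc[s1]
        table.loc[s2, "replicate_index"] = 2
    return ExpressionMatrix(data, paired_or_matrix.layer), CohortDesign(table)


def _random_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 18) -> tuple[str, int]:
    """Random tryptic-like peptide with exactly one cysteine; returns (seq, c_index)."""
    length = int(rng.integers(min_len, max_len + 1))
    body = [str(a) for a in rng.choice(list(AMINO_ACIDS), size=length - 1)]
    c_pos = int(rng.integers(0, length - 1))  # keep C off the C-terminal K/R
    body[c_pos] = "C"
    body.append("K" if rng.random() < 0.5 else "R")
    return "".join(body), c_pos + 1  # 1-based


def generate_psm_table(
    config: SyntheticTruth,
    n_peptides: int,
    n_complete: int,
    design: CohortDesign,
    n_proteins: int | None = None,
    missing_rate: float = 0.3,
    n_decoys: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[PsmTable, SyntheticTruth]:
    """Draw a succinated-peptide PSM table with a planted cohort shift.

    Exactly ``n_complete`` peptides are observed in every sample; each of the
    remaining peptides has at least one missing value (missing-completely-at-
    random at ``missing_rate`` otherwise).  Every true record carries one
    modification of +116.0109 Da on a cysteine; ``n_decoys`` extra records
    carry a wrong residue or wrong mass for validator testing.  Case-cohort
    abundances are shifted by ``config.psm_shift``.
    """
    if n_complete > n_peptides:
        raise SyntheticConfigError("n_complete must be <= n_peptides")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_proteins is None:
        n_proteins = max(1, int(round(n_peptides * 253 / 367)))
    samples = design.sample_ids
    case = _case_cohort(config, design)
    is_case = np.array([design.table.loc[s, "cohort"] == case for s in samples])

    seen: set[str] = set()
    records, abundances = [], []
    while len(records) < n_peptides:
        seq, c_idx = _random_peptide(rng)
        if seq in seen:
            continue
        seen.add(seq)
        if "C" not in seq:
            raise AssertionError("generator invariant violated: peptide without cysteine")
        # cycle so exactly min(n_peptides, n_proteins) accessions are observed
        accession = f"PROT{len(records) % n_proteins + 1:04d}"
        start = int(rng.integers(1, 500))
        baseline = rng.normal(0.0, 1.0)
        values = baseline + config.psm_shift * is_case + rng.normal(0.0, config.psm_noise_sd, len(samples))
        k = len(records)
        if k >= n_complete:  # force >= 1 missing cell so the complete-case count is exact
            miss = rng.random(len(samples)) < missing_rate
            if not miss.any():
                miss[int(rng.integers(0, len(samples)))] = True
            values = np.where(miss, np.nan, values)
        records.append({"peptide": seq, "accession": accession, "start": start,
                        "mods": [(c_idx, "C", SUCCINATION_DELTA_DA)]})
        abundances.append(values)

    for d in range(n_decoys):
        seq, c_idx = _random_peptide(rng)
        if seq in seen:
            continue
        seen.add(seq)
        if d % 2 == 0:  # wrong residue, right mass
            non_c = [i + 1 for i, aa in enumerate(seq) if aa != "C"]
            pos = int(rng.choice(non_c))
            mods = [(pos, seq[pos - 1], SUCCINATION_DELTA_DA)]
        else:  # right residue, wrong mass
            mods = [(c_idx, "C", 120.0)]
        records.append({"peptide": seq, "accession": f"DECOY{d + 1:03d}", "start": 1, "mods": mods})
        abundances.append(rng.normal(0.0, 1.0, len(samples)))

    psms = PsmTable(
        records=pd.DataFrame(records),
        abundance=pd.DataFrame(np.array(abundances), columns=samples),
    )
    return psms, config
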