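"""Cross-ome integration: per-sample mRNA-protein correlation, cohort
comparison, per-pair differential-correlation screening, co-alteration
concordance and external-signature validation.

The central statistic is the per-sample Spearman correlation between a
tumor's protein and transcript profiles over co-quantified genes, compared
between cohorts with a Mann-Whitney U test.  Pair-level screening contrasts
each gene's across-sample protein:transcript correlation within cohort A
versus cohort B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialResult, mwu_test
from .io import CohortDesign, PairedOmics

logger = logging.getLogger(__name__)


class CrossomeError(ValueError):
    pass


@dataclass
class CohortCorrelationComparison:
    """Cohort medians of per-sample cross-ome correlation plus the MWU contrast."""

    median_a: float
    median_b: float
    mwu_u: float
    mwu_p: float
    cohort_a: str
    cohort_b: str


@dataclass
class DifferentialCorrelationScreen:
    """Membership of the pair-level differential-correlation screen.

    ``pair_rhos`` carries rho_A, rho_B and the variability score per gene;
    the three index lists partition out the screened subsets.
    """

    pair_rhos: pd.DataFrame
    variable: list[str]
    a_positive: list[str]
    b_positive: list[str]
    variability_threshold: float
    rho_threshold: float
    metric: str


@dataclass
class CoAlterationTable:
    """Genes significant in both layers, with direction concordance and summary."""

    table: pd.DataFrame
    n_pairs: int
    spearman_rho: float
    spearman_p: float
    n_concordant: int
    q_threshold: float


@dataclass
class ExternalConcordance:
    """Overlap of an internal differential result with an external signature."""

    n_shared: int
    n_significant_raw_p: int
    n_significant_q: int
    rho_raw_p: float
    rho_q: float
    n_not_replicated: int
    rho_not_replicated: float


def zscore_per_sample(data: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (per-sample) z-score over non-missing values.

    A no-op for rank statistics, implemented for fidelity with the study's
    transcript normalization and for any Pearson extension.
    """
    return (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)


def per_sample_correlation(paired: PairedOmics, min_genes: int = 3) -> pd.Series:
    """Spearman correlation between each sample's protein and transcript profiles.

    Uses average-rank ties over the genes co-nonmissing in both layers for
    that sample (pairwise-complete).
    """
    rhos = {}
    for s in paired.sample_ids:
        prot = paired.protein.data[s]
        trans = paired.transcript.data[s]
        ok = prot.notna() & trans.notna()
        if int(ok.sum()) < min_genes:
            raise CrossomeError(f"sample {s!r} has < {min_genes} co-quantified genes")
        rhos[s] = float(stats.spearmanr(prot[ok], trans[ok]).statistic)
        logger.debug("sample %s: %d genes used for cross-ome correlation", s, int(ok.sum()))
    return pd.Series(rhos, name="spearman_rho")


def compare_cohort_correlations(
    rhos: pd.Series, design: CohortDesign, cohorts=None
) -> CohortCorrelationComparison:
    """Cohort medians of per-sample correlations with a two-sided MWU contrast."""
    a, b = cohorts if cohorts is not None else design.cohort_pair()
    rhos_a = rhos[[s for s in design.samples_in(a) if s in rhos.index]]
    rhos_b = rhos[[s for s in design.samples_in(b) if s in rhos.index]]
    if len(rhos_a) < 2 or len(rhos_b) < 2:
        raise CrossomeError("need >= 2 samples per cohort to compare correlations")
    u, p = mwu_test(rhos_a.to_numpy(), rhos_b.to_numpy())
    return CohortCorrelationComparison(
        median_a=float(rhos_a.median()), median_b=float(rhos_b.median()),
        mwu_u=u, mwu_p=p, cohort_a=a, cohort_b=b,
    )


def per_pair_group_correlation(
    paired: PairedOmics, design: CohortDesign, cohorts=None, min_samples: int = 4
) -> pd.DataFrame:
    """Per-gene protein:transcript Spearman across samples, per cohort.

    For each gene, correlates its protein row with its transcript row across
    cohort-A samples and cohort-B samples separately (pairwise-complete).
    Genes with fewer than ``min_samples`` usable samples in either cohort are
    dropped with a log entry.  Returns columns rho_A, rho_B, n_A, n_B.
    """
    a, b = cohorts if cohorts is not None else design.cohort_pair()
    cols = {c: [s for s in design.samples_in(c) if s in paired.sample_ids] for c in (a, b)}
    rows, dropped = {}, 0
    prot, trans = paired.protein.data, paired.transcript.data
    for gene in paired.gene_symbols:
        out = {}
        for label, cohort in (("A", a), ("B", b)):
            p_vals = prot.loc[gene, cols[cohort]]
            t_vals = trans.loc[gene, cols[cohort]]
            ok = p_vals.notna() & t_vals.notna()
            out[f"n_{label}"] = int(ok.sum())
            if out[f"n_{label}"] >= min_samples:
                out[f"rho_{label}"] = float(stats.spearmanr(p_vals[ok], t_vals[ok]).statistic)
        if "rho_A" in out and "rho_B" in out:
            rows[gene] = out
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d pairs with < %d usable samples in a cohort", dropped, min_samples)
    if not rows:
        return pd.DataFrame(columns=["rho_A", "rho_B", "n_A", "n_B"])
    return pd.DataFrame.from_dict(rows, orient="index")[["rho_A", "rho_B", "n_A", "n_B"]]


def differential_correlation_screen(
    pair_rhos: pd.DataFrame,
    variability_threshold: float = 0.5,
    rho_threshold: float = 0.6,
    metric: str = "mad",
) -> DifferentialCorrelationScreen:
    """Screen gene pairs whose cohort correlations diverge.

    The variability score of a pair is the MAD of its two cohort correlations
    {rho_A, rho_B}, which for two numbers equals |rho_A - rho_B| / 2
    (``metric="absdiff"`` uses the full difference instead).  Pairs scoring
    strictly above ``variability_threshold`` are "variable"; within those,
    the A-positive subset has rho_A > rho_threshold and the B-positive
    subset rho_B > rho_threshold.
    """
    if not (0 <= variability_threshold <= 1) or not (0 <= rho_threshold <= 1):
        raise CrossomeError("thresholds must lie in [0, 1]")
    if metric not in ("mad", "absdiff"):
        raise CrossomeError(f"unknown metric {metric!r}")
    df = pair_rhos.copy()
    absdiff = (df["rho_A"] - df["rho_B"]).abs()
    df["variability"] = absdiff / 2.0 if metric == "mad" else absdiff
    variable = df.index[df["variability"] > variability_threshold]
    a_pos = variable[df.loc[variable, "rho_A"] > rho_threshold]
    b_pos = variable[df.loc[variable, "rho_B"] > rho_threshold]
    return DifferentialCorrelationScreen(
        pair_rhos=df,
        variable=list(variable), a_positive=list(a_pos), b_positive=list(b_pos),
        variability_threshold=variability_threshold, rho_threshold=rho_threshold, metric=metric,
    )


def co_altered_pairs(
    diff_protein: DifferentialResult,
    diff_transcript: DifferentialResult,
    q_threshold: float = 0.01,
) -> CoAlterationTable:
    """Genes significant in BOTH layers at q < threshold, with logFC concordance.

    The summary Spearman correlates the protein and transcript log2FC vectors
    over the selected genes; a row is concordant when the two logFCs share a
    sign.
    """
    prot = diff_protein.table
    trans = diff_transcript.table
    shared = prot.index.intersection(trans.index)
    sig = shared[(prot.loc[shared, "q"] < q_threshold) & (trans.loc[shared, "q"] < q_threshold)]
    table = pd.DataFrame(
        {
            "protein_log2FC": prot.loc[sig, "log2FC"],
            "transcript_log2FC": trans.loc[sig, "log2FC"],
            "protein_q": prot.loc[sig, "q"],
            "transcript_q": trans.loc[sig, "q"],
        }
    )
    table["concordant"] = (table["protein_log2FC"] * table["transcript_log2FC"]) > 0
    if len(table) >= 3:
        rho, p = stats.spearmanr(table["protein_log2FC"], table["transcript_log2FC"])
        rho, p = float(rho), float(p)
    else:
        if len(table) == 0:
            logger.warning("no co-altered pairs at q < %g", q_threshold)
        rho, p = float("nan"), float("nan")
    return CoAlterationTable(
        table=table, n_pairs=len(table), spearman_rho=rho, spearman_p=p,
        n_concordant=int(table["concordant"].sum()), q_threshold=q_threshold,
    )


def external_signature_concordance(
    diff: DifferentialResult,
    external: pd.Series | pd.DataFrame,
    p_threshold: float = 0.05,
    q_threshold: float = 0.01,
) -> ExternalConcordance:
    """Replication of an external gene -> log2FC signature in this cohort.

    Counts shared genes significant at the raw-p and adjusted-q thresholds and
    correlates internal with external log2FCs within each subset; the
    non-replicated remainder (raw p >= threshold) is reported with its own
    correlation.
    """
    if isinstance(external, pd.DataFrame):
        external = external.iloc[:, 0]
    external = external.astype(float)
    shared = diff.table.index.intersection(external.index)
    if len(shared) < 3:
        raise CrossomeError("need >= 3 genes shared with the external signature")
    internal = diff.table.loc[shared]

    def _rho(genes) -> float:
        if len(genes) < 3:
            return float("nan")
        return float(stats.spearmanr(internal.loc[genes, "log2FC"], external[genes]).statistic)

    sig_p = shared[internal["p"] < p_threshold]
    sig_q = shared[internal["q"] < q_threshold]
    rest = shared[internal["p"] >= p_threshold]
    return ExternalConcordance(
        n_shared=len(shared),
        n_significant_raw_p=len(sig_p), n_significant_q=len(sig_q),
        rho_raw_p=_rho(sig_p), rho_q=_rho(sig_q),
        n_not_replicated=len(rest), rho_not_replicated=_rho(rest),
    )
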