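"""Cysteine succination (2SC) PTM analysis.

S-(2-succino)cysteine is the non-enzymatic adduct formed when accumulated
fumarate reacts with cysteine thiols, adding a C4H4O4 group (+116.0109 Da
monoisotopic).  This module validates 2SC peptide-spectrum matches by their
cysteine mass delta, rolls PSMs up to unique modified peptides, filters to
complete-case peptides, maps modified residues to protein coordinates, and
stratifies cohorts on the filtered matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .differential import mwu_test
from .io import CohortDesign, ExpressionMatrix, PsmTable

logger = logging.getLogger(__name__)

#: Monoisotopic mass delta of the 2SC (fumarate) adduct, Da.
SUCCINATION_DELTA_DA = 116.0109

_ELEMENT_TOKEN = re.compile(r"(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?)\(?(?P<count>\d+)?\)?")


class SuccinationError(ValueError):
    pass


@dataclass(frozen=True)
class ElementalComposition:
    """Element (or labeled isotope such as 13C, 15N) -> nonnegative count."""

    counts: tuple

    @classmethod
    def parse(cls, formula: str | dict) -> "ElementalComposition":
        """Parse ``"C4H4O4"``, ``"H(20) C(8) 13C(4) N(1) 15N(1) O(2)"`` or a dict.

        Isotope labels are written as a leading mass number (``13C``).  Unknown
        element symbols are rejected here, not at mass time.
        """
        if isinstance(formula, dict):
            items = list(formula.items())
        else:
            items = []
            text = formula.replace(" ", " ").strip()
            pos = 0
            for token in text.split():
                for m in _ELEMENT_TOKEN.finditer(token):
                    if not m.group(0):
                        continue
                    key = (m.group("isotope") or "") + m.group("element")
                    items.append((key, int(m.group("count") or 1)))
            if not items:
                raise SuccinationError(f"cannot parse composition {formula!r}")
        counts: dict[str, int] = {}
        for key, count in items:
            if count < 0:
                raise SuccinationError(f"negative count for {key!r}")
            m = re.fullmatch(r"(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?)", str(key))
            if m is None:
                raise SuccinationError(f"bad element token {key!r}")
            element = m.group("element")
            isotope = int(m.group("isotope")) if m.group("isotope") else 0
            if element not in _ptmass.nist_mass:
                raise SuccinationError(f"unknown element {element!r}")
            if isotope and isotope not in _ptmass.nist_mass[element]:
                raise SuccinationError(f"unknown isotope {isotope}{element}")
            k = f"{isotope or ''}{element}"
            counts[k] = counts.get(k, 0) + count
        return cls(counts=tuple(sorted(counts.items())))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for k, v in other.counts:
            merged[k] = merged.get(k, 0) + v
        return ElementalComposition(counts=tuple(sorted(merged.items())))


def monoisotopic_mass(composition: ElementalComposition | str | dict) -> float:
    """Monoisotopic mass in Da of an elemental composition.

    Plain element symbols use the most-abundant-isotope mass; labeled tokens
    (13C, 15N, ...) use that isotope's mass.  Atomic masses come from the
    NIST table shipped with pyteomics.  Additive over compositions.
    """
    if not isinstance(composition, ElementalComposition):
        composition = ElementalComposition.parse(composition)
    total = 0.0
    for key, count in composition.counts:
        m = re.fullmatch(r"(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?)", key)
        element = m.group("element")
        isotope = int(m.group("isotope")) if m.group("isotope") else 0
        table = _ptmass.nist_mass[element]
        total += count * (table[isotope][0] if isotope else table[0][0])
    return total


def validate_2sc_psms(psms: PsmTable, tolerance: float = 0.01) -> tuple[PsmTable, pd.DataFrame]:
    """Keep PSMs carrying a genuine 2SC modification; categorize the rest.

    A record is accepted iff at least one modification sits on a cysteine
    (the annotated residue letter must match the sequence) with
    |delta - 116.0109| <= tolerance.  Rejections are categorized as
    wrong_residue, wrong_mass or malformed (bad index / letter mismatch).
    """
    if tolerance <= 0:
        raise SuccinationError("tolerance must be positive")
    accepted_idx, rows = [], []
    for i, rec in psms.records.iterrows():
        seq = rec["peptide"]
        category = "no_modification"
        accepted = False
        for idx, res, delta in rec["mods"]:
            if not (1 <= idx <= len(seq)) or seq[idx - 1] != res:
                category = "malformed"
                continue
            mass_ok = abs(delta - SUCCINATION_DELTA_DA) <= tolerance
            if res == "C" and mass_ok:
                accepted = True
                break
            category = "wrong_residue" if res != "C" else "wrong_mass"
        if accepted:
            accepted_idx.append(i)
        else:
            rows.append({"peptide": seq, "accession": rec["accession"], "category": category})
    report = pd.DataFrame(rows, columns=["peptide", "accession", "category"])
    kept = PsmTable(
        records=psms.records.loc[accepted_idx].reset_index(drop=True),
        abundance=psms.abundance.loc[accepted_idx].reset_index(drop=True),
    )
    logger.info("2SC validation: %d accepted, %d rejected", len(kept), len(report))
    return kept, report


def _peptide_key(rec) -> str:
    indices = sorted({idx for idx, res, delta in rec["mods"]
                      if res == "C" and abs(delta - SUCCINATION_DELTA_DA) <= 0.5})
    return rec["peptide"] + "|" + ",".join(map(str, indices))


def rollup_unique(psms: PsmTable) -> tuple[int, int, ExpressionMatrix]:
    """Collapse accepted PSMs to unique modified peptides.

    Uniqueness key = (peptide sequence, set of 2SC-modified residue indices),
    so positional isomers count separately.  Per-sample abundance per key is
    the median over contributing PSMs.  Returns (unique peptide count,
    distinct accession count, peptide x sample matrix).
    """
    if len(psms) == 0:
        raise SuccinationError("no accepted PSMs to roll up")
    keys = psms.records.apply(_peptide_key, axis=1)
    matrix = psms.abundance.groupby(keys.values).median()
    n_proteins = psms.records["accession"].nunique()
    return len(matrix), int(n_proteins), ExpressionMatrix(matrix, "psm")


def completeness_filter(matrix: ExpressionMatrix, mode: str = "all-samples") -> ExpressionMatrix:
    """Retain peptides observed in every sample (complete-case rows)."""
    if mode != "all-samples":
        raise SuccinationError(f"unknown completeness mode {mode!r}")
    complete = matrix.data.dropna()
    logger.info("completeness filter: %d of %d peptides retained", len(complete), len(matrix.data))
    if complete.empty:
        logger.warning("no peptides observed across all samples")
    return ExpressionMatrix(complete, matrix.layer)


@dataclass
class SuccinationStratification:
    """Cohort stratification of the complete-case 2SC peptide matrix."""

    median_group_difference: float
    mwu_u: float
    mwu_p: float
    pca_variance_explained: np.ndarray
    per_peptide_differences: pd.Series
    cohort_a: str
    cohort_b: str


def stratify_2sc(matrix: ExpressionMatrix, design: CohortDesign, cohorts=None) -> SuccinationStratification:
    """Headline cohort contrast of succinated-peptide abundance.

    Per peptide: median(A) - median(B); the headline statistic is the median
    of those per-peptide differences.  The MWU p contrasts per-sample mean
    2SC abundance between cohorts; PCA (samples as observations, peptides
    centered, unscaled) gives the variance-explained spectrum.
    """
    from .stratify import pca  # local import to avoid a cycle

    if matrix.data.empty:
        raise SuccinationError("empty filtered 2SC matrix")
    a, b = cohorts if cohorts is not None else design.cohort_pair()
    cols_a = [s for s in design.samples_in(a) if s in matrix.data.columns]
    cols_b = [s for s in design.samples_in(b) if s in matrix.data.columns]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise SuccinationError("need >= 2 samples per cohort")
    diffs = matrix.data[cols_a].median(axis=1) - matrix.data[cols_b].median(axis=1)
    sample_means = matrix.data[cols_a + cols_b].mean(axis=0)
    u, p = mwu_test(sample_means[cols_a].to_numpy(), sample_means[cols_b].to_numpy())
    pca_res = pca(ExpressionMatrix(matrix.data[cols_a + cols_b], matrix.layer))
    return SuccinationStratification(
        median_group_difference=float(diffs.median()),
        mwu_u=u, mwu_p=p,
        pca_variance_explained=pca_res.variance_explained,
        per_peptide_differences=diffs,
        cohort_a=a, cohort_b=b,
    )


def map_modified_residue(record: pd.Series | dict, mod_index: int | None = None) -> str:
    """Protein-coordinate label of a modified residue, e.g. ``"C283"``.

    Protein position = start offset + peptide index - 1.  With no explicit
    ``mod_index`` the record's first modification is used.
    """
    seq = record["peptide"]
    start = int(record["start"])
    if mod_index is None:
        if not record["mods"]:
            raise SuccinationError("record has no modifications")
        idx, res, _ = record["mods"][0]
    else:
        idx = mod_index
        if not (1 <= idx <= len(seq)):
            raise SuccinationError(f"modification index {idx} outside peptide of length {len(seq)}")
        res = seq[idx - 1]
    if not (1 <= idx <= len(seq)):
        raise SuccinationError(f"modification index {idx} outside peptide of length {len(seq)}")
    if start < 1:
        raise SuccinationError("start offset must be >= 1")
    return f"{res}{start + idx - 1}"


def annotate_functional_residues(psms: PsmTable, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join residue-level functional notes onto accepted 2SC records.

    ``annotations`` is keyed by columns (accession, residue) with a ``note``
    column, emulating curated knowledgebase metadata about the modified
    cysteine.  Returns one row per record with its residue label and note
    (empty when unannotated); annotated/unannotated counts are logged.
    """
    rows = []
    for _, rec in psms.records.iterrows():
        rows.append({
            "peptide": rec["peptide"],
            "accession": rec["accession"],
            "residue": map_modified_residue(rec),
        })
    out = pd.DataFrame(rows)
    if annotations is not None and not annotations.empty:
        out = out.merge(annotations[["accession", "residue", "note"]], on=["accession", "residue"], how="left")
    else:
        out["note"] = pd.NA
    out["note"] = out["note"].fillna("")
    n_annot = int((out["note"] != "").sum())
    logger.info("functional annotation: %d annotated, %d unannotated", n_annot, len(out) - n_annot)
    return out
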