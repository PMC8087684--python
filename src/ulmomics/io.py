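"""Containers and file I/O for expression matrices, cohort designs, PSM tables and gene sets.

All abundance matrices are features x samples on the log2 scale with NaN as
the missing marker.  Design tables map samples to cohorts (exactly two levels
for the two-group machinery), patients and technical-replicate indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_LAYERS = ("protein", "transcript", "psm")

#: TSV cells treated as missing on read.
NA_VALUES = ["", "NA"]


class OmicsIOError(ValueError):
    """Raised for malformed input files or incompatible matrices."""


@dataclass
class ExpressionMatrix:
    """A features x samples log2 abundance matrix for one ome layer.

    Parameters
    ----------
    data:
        DataFrame indexed by unique feature ids (gene symbols or peptide
        keys) with unique sample-id columns; NaN marks missing values.
    layer:
        One of ``protein``, ``transcript`` or ``psm``.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise OmicsIOError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate feature ids after collapse: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate sample ids: {dupes}")
        if np.isinf(self.data.to_numpy(dtype=float, na_value=np.nan)).any():
            raise OmicsIOError("non-finite (infinite) abundance values are not allowed")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def drop_empty_features(self) -> "ExpressionMatrix":
        """Drop features with no observed value in any sample."""
        keep = self.data.notna().any(axis=1)
        if (~keep).any():
            logger.info("dropping %d features with no observed values", int((~keep).sum()))
        return ExpressionMatrix(self.data.loc[keep], self.layer)


@dataclass
class CohortDesign:
    """Sample annotation: cohort label plus optional patient / replicate structure.

    ``table`` is indexed by sample_id with columns ``cohort`` and optionally
    ``patient_id``, ``replicate_index`` (integer >= 1) and ``ancestry``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "cohort" not in self.table.columns:
            raise OmicsIOError("design table needs a 'cohort' column")
        if self.table.index.duplicated().any():
            raise OmicsIOError("duplicate sample ids in design table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def cohort_levels(self) -> list[str]:
        """Cohort labels in order of first appearance."""
        return list(pd.unique(self.table["cohort"]))

    def cohort_pair(self) -> tuple[str, str]:
        levels = self.cohort_levels()
        if len(levels) != 2:
            raise OmicsIOError(f"expected exactly two cohorts, found {levels}")
        return levels[0], levels[1]

    def samples_in(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == cohort])

    def subset(self, sample_ids) -> "CohortDesign":
        present = [s for s in sample_ids if s in self.table.index]
        return CohortDesign(self.table.loc[present])

    @classmethod
    def from_tsv(cls, path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=NA_VALUES, keep_default_na=False)
        if "sample_id" not in df.columns:
            raise OmicsIOError("design table needs a 'sample_id' column")
        df = df.set_index("sample_id")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class PairedOmics:
    """Protein and transcript matrices aligned on shared genes and samples."""

    protein: ExpressionMatrix
    transcript: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.protein.feature_ids != self.transcript.feature_ids:
            raise OmicsIOError("paired layers must share identical feature ordering")
        if self.protein.sample_ids != self.transcript.sample_ids:
            raise OmicsIOError("paired layers must share identical sample ordering")

    @property
    def gene_symbols(self) -> list[str]:
        return self.protein.feature_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.protein.sample_ids


@dataclass
class GeneSet:
    """A named set of uppercase gene symbols."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise OmicsIOError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in self.symbols))


@dataclass
class PsmTable:
    """Modification-resolved peptide-spectrum records with per-sample abundances.

    ``records`` holds one row per PSM with columns ``peptide`` (uppercase
    amino-acid letters), ``accession``, ``start`` (1-based offset of peptide
    residue 1 in the protein) and ``mods`` (list of
    ``(peptide_index, residue_letter, delta_mass_da)`` tuples).
    ``abundance`` holds the matching per-sample log2 reporter values.
    """

    records: pd.DataFrame
    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peptide", "accession", "start", "mods"}
        missing = required - set(self.records.columns)
        if missing:
            raise OmicsIOError(f"PSM table missing columns: {sorted(missing)}")
        if len(self.records) != len(self.abundance):
            raise OmicsIOError("records and abundance row counts differ")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)


def _format_mods(mods) -> str:
    return ";".join(f"{i}|{res}|{delta:.4f}" for i, res, delta in mods)


def _parse_mods(text: str):
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for token in text.split(";"):
        idx, res, delta = token.split("|")
        out.append((int(idx), res, float(delta)))
    return out


def read_expression_matrix(path, layer: str) -> ExpressionMatrix:
    """Read a features x samples TSV (first column = feature id) into a matrix.

    Duplicate feature ids are collapsed by the per-sample median, a robust,
    order-independent rule.  Non-numeric cells and duplicate sample ids are
    errors; empty cells and ``NA`` are missing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise OmicsIOError(f"{path}: need a feature id column plus >= 1 sample column")
    if pd.Index(header[1:]).duplicated().any():
        raise OmicsIOError(f"{path}: duplicate sample ids in header")
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=NA_VALUES, keep_default_na=False)
    sample_cols = list(header[1:])
    raw.columns = header
    if raw.empty:
        raise OmicsIOError(f"{path}: no features")

    features = raw.iloc[:, 0]
    values = raw.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise OmicsIOError(
            f"{path}: non-numeric cell {values.iat[r, c]!r} at feature "
            f"{features.iat[r]!r}, sample {sample_cols[c]!r}"
        )
    numeric = values.astype(float)  # correctly-rounded parse (to_numeric's fast path is lossy)
    numeric.index = features
    n_before = len(numeric)
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).median()
        logger.info("collapsed %d duplicate feature rows by median", n_before - len(numeric))
    matrix = ExpressionMatrix(numeric, layer).drop_empty_features()
    if matrix.shape[0] == 0:
        raise OmicsIOError(f"{path}: no features")
    logger.info("read %s matrix: %d features x %d samples", layer, *matrix.shape)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    # %.17g round-trips IEEE doubles bit-exactly through text
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA", float_format="%.17g")


def match_features(protein: ExpressionMatrix, transcript: ExpressionMatrix) -> PairedOmics:
    """Pair the two omes on case-folded gene symbols and shared samples.

    Symbols are uppercased before intersection (no alias resolution); rows
    sharing an uppercased symbol within one layer are collapsed by median.
    The paired gene order is sorted for determinism.
    """

    def _fold(m: ExpressionMatrix) -> pd.DataFrame:
        df = m.data.copy()
        df.index = df.index.str.upper()
        if df.index.duplicated().any():
            df = df.groupby(level=0, sort=False).median()
        return df

    prot, trans = _fold(protein), _fold(transcript)
    genes = sorted(set(prot.index) & set(trans.index))
    samples = [s for s in prot.columns if s in set(trans.columns)]
    if not genes or not samples:
        raise OmicsIOError(
            f"no shared genes/samples to pair (shared genes={len(genes)}, shared samples={len(samples)})"
        )
    logger.info(
        "matched %d genes (%d protein-only, %d transcript-only) over %d shared samples",
        len(genes), len(prot.index) - len(genes), len(trans.index) - len(genes), len(samples),
    )
    return PairedOmics(
        protein=ExpressionMatrix(prot.loc[genes, samples], "protein"),
        transcript=ExpressionMatrix(trans.loc[genes, samples], "transcript"),
    )


def collapse_replicates(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    low_correlation_threshold: float = 0.3,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain technical replicate #1 per patient; report replicate Spearman QC.

    For every patient with k > 1 replicate columns, all pairwise Spearman
    correlations over co-nonmissing features are computed and pairs below
    ``low_correlation_threshold`` are flagged.  The replicate with
    ``replicate_index == 1`` is kept; values of retained columns are never
    altered.
    """
    table = design.table
    if "replicate_index" not in table.columns or "patient_id" not in table.columns:
        return matrix, pd.DataFrame(columns=["patient_id", "sample_a", "sample_b", "spearman_rho", "low_correlation"])

    rows = []
    drop: list[str] = []
    rep = table[table["replicate_index"].notna()]
    for patient, group in rep.groupby("patient_id"):
        samples = [s for s in group.index if s in matrix.data.columns]
        if len(samples) < 2:
            continue
        idx = group.loc[samples, "replicate_index"].astype(int)
        if 1 not in idx.values:
            raise OmicsIOError(f"patient {patient!r} has replicates but none with replicate_index = 1")
        keep = idx.index[idx == 1][0]
        drop.extend(s for s in samples if s != keep)
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                both = matrix.data[[a, b]].dropna()
                rho = float(stats.spearmanr(both[a], both[b]).statistic) if len(both) >= 3 else np.nan
                rows.append({
                    "patient_id": patient, "sample_a": a, "sample_b": b,
                    "spearman_rho": rho,
                    "low_correlation": bool(rho < low_correlation_threshold) if np.isfinite(rho) else True,
                })
    report = pd.DataFrame(rows, columns=["patient_id", "sample_a", "sample_b", "spearman_rho", "low_correlation"])
    if report.empty:
        return matrix, report
    kept = [c for c in matrix.data.columns if c not in set(drop)]
    for _, row in report.iterrows():
        if row["low_correlation"]:
            logger.warning(
                "low replicate correlation for patient %s: %s vs %s (rho=%.3f)",
                row["patient_id"], row["sample_a"], row["sample_b"], row["spearman_rho"],
            )
    return ExpressionMatrix(matrix.data[kept], matrix.layer), report


def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file (name, description, tab-separated symbols) into gene sets."""
    sets: list[GeneSet] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise OmicsIOError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name, _desc, *symbols = fields
        symbols = [s.upper() for s in symbols if s.strip()]
        if len(symbols) != len(set(symbols)):
            logger.warning("%s:%d: duplicated symbols in gene set %r dropped", path, lineno, name)
        sets.append(GeneSet(name=name, symbols=frozenset(symbols)))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def read_psm_table(path) -> PsmTable:
    """Read a PSM CSV/TSV: peptide, accession, start, mods, then sample columns.

    ``mods`` is a semicolon list of ``index|residue|delta`` tokens.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False)
    required = ["peptide", "accession", "start", "mods"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OmicsIOError(f"{path}: PSM table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    records = df[required].copy()
    records["mods"] = records["mods"].map(_parse_mods)
    records["start"] = records["start"].astype(int)
    abundance = df[sample_cols].astype(float)
    return PsmTable(records=records, abundance=abundance)


def write_psm_table(psms: PsmTable, path) -> None:
    out = psms.records.copy()
    out["mods"] = out["mods"].map(_format_mods)
    out = pd.concat([out.reset_index(drop=True), psms.abundance.reset_index(drop=True)], axis=1)
    sep = "," if str(path).endswith(".csv") else "\t"
    out.to_csv(path, sep=sep, index=False, na_rep="NA")
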