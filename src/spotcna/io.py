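"""Readers and writers for the on-disk formats.

Counts come in as MatrixMarket triplets (matrix.mtx + barcodes.tsv +
features.tsv) or as a dense TSV; coordinates and annotations are small CSVs
keyed by bead id; gene positions are the 4-column TSV dialect of the Broad
CTAT gene-ordering files (gene, chromosome, start, end), with the p/q arm
derived from a bundled centromere table (hg38 or hg19) or a user table.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    FormatError,
    GenePositions,
    SpatialExpression,
    ValidationError,
)

log = logging.getLogger(__name__)

_BUNDLED_CENTROMERES = {"hg38": "centromeres_hg38.tsv", "hg19": "centromeres_hg19.tsv"}


def load_centromeres(source: str | Path = "hg38") -> pd.Series:
    """Centromere position per chromosome (chromosome -> bp).

    ``source`` is ``"hg38"``, ``"hg19"``, or a path to a two-column TSV
    (chromosome, position) for custom genomes.
    """
    if isinstance(source, str) and source in _BUNDLED_CENTROMERES:
        ref = resources.files("spotcna.data") / _BUNDLED_CENTROMERES[source]
        with resources.as_file(ref) as path:
            table = pd.read_csv(path, sep="\t")
    else:
        table = pd.read_csv(source, sep="\t")
        if table.shape[1] < 2:
            raise FormatError(f"centromere table {source} needs 2 columns")
        table.columns = ["chromosome", "position", *table.columns[2:]]
    return pd.Series(table["position"].values, index=table["chromosome"].values)


def _normalize_chrom(chrom: pd.Series) -> pd.Series:
    chrom = chrom.astype(str)
    bare = ~chrom.str.startswith("chr")
    chrom = chrom.where(~bare, "chr" + chrom)
    return chrom.replace({"chrMT": "chrM", "chr23": "chrX"})


def read_gene_positions(path: str | Path, centromeres: str | Path = "hg38") -> GenePositions:
    """Read a gene-position TSV and assign chromosome arms.

    The file has >= 4 columns (gene, chromosome, start, end); a header row is
    auto-detected (first row whose third field is non-numeric). Duplicate gene
    symbols keep the first occurrence; genes on chromosomes absent from the
    centromere table are flagged with arm ``p`` and a warning, not dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if raw.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 tab-separated columns, got {raw.shape[1]}")
    first = str(raw.iloc[0, 2])
    has_header = not first.strip().lstrip("-").isdigit()
    if has_header:
        raw = raw.iloc[1:].reset_index(drop=True)
    table = raw.iloc[:, :4].copy()
    table.columns = ["gene", "chromosome", "start", "end"]
    for col in ("start", "end"):
        parsed = pd.to_numeric(table[col], errors="coerce")
        if parsed.isna().any():
            offset = 2 if has_header else 1  # 1-based line number in the file
            line = int(parsed.index[parsed.isna()][0]) + offset
            raise FormatError(f"{path}: unparseable {col} coordinate at line {line}")
        table[col] = parsed.astype(np.int64)
    table["chromosome"] = _normalize_chrom(table["chromosome"])

    dup = table["gene"].duplicated()
    if dup.any():
        log.warning("gene position file: dropping %d duplicated symbols (keeping first)", int(dup.sum()))
        table = table.loc[~dup]

    centro = load_centromeres(centromeres)
    known = table["chromosome"].isin(centro.index)
    if not known.all():
        missing = sorted(table.loc[~known, "chromosome"].unique())
        log.warning("no centromere for chromosomes %s; arm set to 'p'", missing)
    pos = table["chromosome"].map(centro)
    table["arm"] = np.where(pos.notna() & (table["start"].values >= pos.fillna(np.inf).values), "q", "p")
    return GenePositions(table.reset_index(drop=True))


def _check_integer(frame: pd.DataFrame, path) -> pd.DataFrame:
    vals = frame.to_numpy()
    if not np.isfinite(vals).all():
        raise FormatError(f"{path}: non-finite count entries")
    if np.any(vals != np.round(vals)):
        raise FormatError(f"{path}: non-integer count entries")
    return frame.astype(np.int64)


def read_counts(
    path: str | Path,
    dialect: str = "mtx_triplet",
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Read a bead x gene count matrix.

    dialect ``mtx_triplet``: ``path`` is a directory holding ``matrix.mtx``,
    ``barcodes.tsv`` (beads) and ``features.tsv`` (genes); the matrix is
    genes x beads as in CellRanger output. Beads with no explicit entries are
    retained as all-zero rows.

    dialect ``dense_tsv``: ``path`` is a labelled TSV, beads x genes or
    genes x beads; orientation is auto-detected by matching labels against
    ``genes`` when given (otherwise rows are taken as beads).
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mat = scipy.io.mmread(path / "matrix.mtx")
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        dense = np.asarray(scipy.sparse.csr_matrix(mat).todense()).T  # -> beads x genes
        if dense.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        frame = pd.DataFrame(dense, index=barcodes, columns=features)
    elif dialect == "dense_tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        if genes is not None:
            gene_set = set(genes)
            row_hits = frame.index.isin(gene_set).mean()
            col_hits = frame.columns.isin(gene_set).mean()
            if row_hits > col_hits:
                frame = frame.T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame.index.name = None
    frame.columns.name = None
    if frame.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate bead ids")
    if frame.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    frame = _check_integer(frame, path)
    # canonical ordering so reader output is independent of file row order
    return frame.sort_index(axis=0)


def attach_metadata(
    counts: pd.DataFrame,
    coords_path: str | Path,
    annotation_path: str | Path,
) -> SpatialExpression:
    """Join counts with coordinates and malignancy annotations.

    Beads missing coordinates or annotation are dropped (with a logged
    count); zero reference beads after the join is a hard error.
    """
    coords = pd.read_csv(coords_path)
    coords.columns = [c.strip().lower() for c in coords.columns]
    for col in ("bead", "x", "y"):
        if col not in coords.columns:
            raise FormatError(f"{coords_path}: missing column {col!r}")
    coords = coords.set_index(coords["bead"].astype(str))[["x", "y"]].astype(float)

    anno = pd.read_csv(annotation_path)
    anno.columns = [c.strip().lower() for c in anno.columns]
    for col in ("bead", "type"):
        if col not in anno.columns:
            raise FormatError(f"{annotation_path}: missing column {col!r}")
    types = anno.set_index(anno["bead"].astype(str))["type"].astype(str).str.strip()
    types = types.replace({"normal": "non_reference_normal"})

    keep = counts.index.intersection(coords.index).intersection(types.index)
    dropped = len(counts.index) - len(keep)
    if dropped:
        log.info("attach_metadata: dropped %d beads missing coordinates or annotation", dropped)
    if len(keep) == 0:
        raise ValidationError("no beads left after joining coordinates and annotations")
    keep = keep.sort_values()
    se = SpatialExpression(counts.loc[keep], coords.loc[keep], types.loc[keep])
    if int(se.is_reference.sum()) == 0:
        raise ValidationError("reference population required")
    return se


# ---------------------------------------------------------------------------
# writers

def write_counts_mtx(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write beads x genes counts as genes x beads matrix.mtx + label TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.to_numpy().T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    pd.Series(counts.index).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)


def write_coords(coords: pd.DataFrame, path: str | Path) -> None:
    out = coords.reset_index()
    out.columns = ["bead", "x", "y"]
    out.to_csv(path, index=False)


def write_annotations(bead_type: pd.Series, path: str | Path) -> None:
    out = bead_type.replace({"non_reference_normal": "normal"}).reset_index()
    out.columns = ["bead", "type"]
    out.to_csv(path, index=False)


def write_gene_positions(gp: GenePositions, path: str | Path) -> None:
    gp.table[["gene", "chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )
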