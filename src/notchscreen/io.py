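"""Readers and writers for the pipeline's tab-delimited and FASTA formats.

All tabular outputs are TSV with ``#``-prefixed comment lines carrying the
package version and the parameters of the producing stage, so every file is
self-describing and byte-reproducible under a fixed seed.

Promoter FASTA headers follow ``gene|species|start..end|strand`` with
TSS-relative, 1-based-style coordinates in the +1 convention (no position 0):
the default 601 nt window is ``-500..+101``.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .motifs import PromoterWindow, PromoterWindowSpec, extract_window


def _header_lines(params: dict | None) -> str:
    from . import __version__

    lines = [f"# notchscreen {__version__}"]
    for key in sorted(params or {}):
        lines.append(f"# {key}={params[key]}")
    return "".join(line + "\n" for line in lines)


def write_table(df: pd.DataFrame, path, params: dict | None = None, index: bool = False) -> None:
    """TSV with commented provenance header; floats at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g", lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_expression(
    matrix: ExpressionMatrix, path, conditions_path=None, params: dict | None = None
) -> None:
    """Genes-by-samples TSV plus a sidecar sample->condition map."""
    write_table(matrix.intensities.rename_axis("gene"), path, params, index=True)
    if conditions_path is not None:
        cond = matrix.conditions.rename_axis("sample").rename("condition").reset_index()
        write_table(cond, conditions_path, params)


def read_expression(path, conditions_path) -> ExpressionMatrix:
    intensities = read_table(path, index_col="gene")
    cond = read_table(conditions_path)
    return ExpressionMatrix(intensities, pd.Series(cond["condition"].to_numpy(),
                                                   index=cond["sample"]))


def write_go_table(pairs: pd.DataFrame, path, params: dict | None = None) -> None:
    write_table(pairs[["gene", "term"]], path, params)


def read_go_table(path) -> pd.DataFrame:
    return read_table(path, names=["gene", "term"], header=0)


_HEADER_RE = re.compile(r"^(?P<gene>[^|]+)\|(?P<species>[^|]+)\|(?P<start>[+-]?\d+)\.\.(?P<end>[+-]?\d+)\|(?P<strand>[+-])$")


def window_coords(spec: PromoterWindowSpec) -> tuple[int, int]:
    """TSS-relative first..last coordinates of a full window (+1 convention)."""
    start = -spec.upstream if spec.upstream else 1
    return start, spec.downstream + 1


def write_promoters(windows, path) -> None:
    """Multi-FASTA with ``gene|species|start..end|strand`` headers."""
    records = []
    for w in sorted(windows, key=lambda w: (w.gene, w.species)):
        start, end = window_coords(w.spec)
        rid = f"{w.gene}|{w.species}|{start:+d}..{end:+d}|+"
        records.append(SeqRecord(Seq(w.seq), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path) -> list[PromoterWindow]:
    """Parse promoter windows back from the FASTA header convention."""
    windows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(rec.id)
        if not m:
            raise ValueError(f"unrecognized promoter header {rec.id!r}")
        start, end = int(m["start"]), int(m["end"])
        upstream = -start if start < 0 else 0
        downstream = end - 1 if end > 0 else 0
        spec = PromoterWindowSpec(upstream=upstream, downstream=downstream)
        windows.append(
            PromoterWindow(gene=m["gene"], species=m["species"], seq=str(rec.seq),
                           spec=spec)
        )
    return windows


def read_tss_table(path) -> pd.DataFrame:
    """BED-like stranded TSS table: record id, 1-based TSS, strand, gene[, species].

    The 1-based TSS column is converted to the 0-based index expected by
    :func:`notchscreen.motifs.extract_window`.
    """
    cols = ["record", "tss", "strand", "gene", "species"]
    table = read_table(path, names=cols, header=None).dropna(axis=1, how="all")
    table.columns = cols[: table.shape[1]]
    table["tss_index"] = table["tss"].astype(int) - 1
    return table


def windows_from_genome(fasta_path, tss_table: pd.DataFrame,
                        spec: PromoterWindowSpec | None = None) -> list[PromoterWindow]:
    """Extract TSS-anchored windows from chromosome FASTA + a TSS table."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    windows = []
    for row in tss_table.itertuples():
        species = getattr(row, "species", "")
        windows.append(
            extract_window(seqs[row.record], int(row.tss_index), row.strand,
                           spec, gene=row.gene, species=species)
        )
    return windows


def read_series_matrix(path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Minimal GEO series-matrix text parser.

    Returns the probe-by-sample value table (index = ID_REF) and the
    ``!Sample_*`` metadata lines keyed by tag.  Supports the plain-text,
    uncompressed form of a series matrix; intended for the optional
    accession-based re-analysis mode.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
            elif line.startswith("!series_matrix_table_end"):
                in_table = False
            elif in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                tag, _, rest = line[1:].partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                meta.setdefault(tag, []).extend(values)
    if not table_lines:
        raise ValueError(f"no series_matrix table found in {path}")
    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    frame.index.name = "ID_REF"
    frame.columns = [c.strip('"') for c in frame.columns]
    return frame, meta
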