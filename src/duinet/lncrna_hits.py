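"""lncRNA genome-hit filtering, gene containment and resampling enrichment.

Sequence-similarity hits of candidate lncRNAs against the genome are kept
when they are longer than 100 bp, cover more than 50% of the lncRNA and
exceed 90% identity (strict inequalities).  Surviving hits are assigned
to genes when fully contained within the gene body extended by a 100 bp
flank, with sense/antisense orientation relative to the host gene.  The
over-representation of hits inside a focal (differentially expressed)
gene set is assessed against random gene sets of the same size resampled
from the universe.

Coordinates are 0-based half-open internally; the common 1-based
inclusive tabular dialect is converted on read.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "read_hit_table",
    "read_gene_intervals",
    "filter_hits",
    "annotate_containment",
    "hit_enrichment",
]

HIT_COLUMNS = [
    "query_id",
    "query_length",
    "seqid",
    "start",
    "end",
    "strand",
    "identity",
    "length",
    "coverage",
]


def read_hit_table(
    path,
    query_lengths: dict[str, int] | None = None,
    one_based: bool = True,
) -> pd.DataFrame:
    """Read 12-column tabular similarity hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Strand is inferred from subject
    coordinate order; coverage needs ``query_lengths`` (qseqid -> length).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
    fwd = df["sstart"] <= df["send"]
    start = np.where(fwd, df["sstart"], df["send"]).astype(int)
    end = np.where(fwd, df["send"], df["sstart"]).astype(int)
    if one_based:
        start = start - 1  # half-open
    qlen = (
        df["qseqid"].map(query_lengths)
        if query_lengths is not None
        else np.abs(df["qend"] - df["qstart"]) + 1
    )
    cov = (np.abs(df["qend"] - df["qstart"]) + 1) / qlen
    return pd.DataFrame(
        {
            "query_id": df["qseqid"],
            "query_length": qlen,
            "seqid": df["sseqid"],
            "start": start,
            "end": end,
            "strand": np.where(fwd, "+", "-"),
            "identity": df["pident"],
            "length": df["length"],
            "coverage": cov,
        }
    )


def read_gene_intervals(path, one_based: bool = True) -> pd.DataFrame:
    """GFF-like TSV: seqid, start, end, strand, gene_id[, focal]."""
    df = pd.read_csv(path, sep="\t")
    if one_based:
        df = df.assign(start=df["start"] - 1)
    if "focal" not in df.columns:
        df["focal"] = False
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} intervals with start >= end")
    return df


def filter_hits(
    hits: pd.DataFrame,
    min_len: float = 100,
    min_cov: float = 0.5,
    min_ident: float = 90,
) -> pd.DataFrame:
    """Strict thresholds: length > 100 bp, coverage > 0.5, identity > 90."""
    keep = (
        (hits["length"] > min_len)
        & (hits["coverage"] > min_cov)
        & (hits["identity"] > min_ident)
    )
    return hits[keep].reset_index(drop=True)


def annotate_containment(
    hits: pd.DataFrame, genes: pd.DataFrame, flank: int = 100
) -> pd.DataFrame:
    """Assign hits to genes containing them (gene body +/- flank).

    A hit maps to gene g when ``g.start - flank <= hit.start`` and
    ``hit.end <= g.end + flank`` on the same sequence.  Hits overlapping
    several genes yield one row per assignment; orientation is antisense
    when hit and gene strands differ.  Hits on sequences absent from the
    gene table are dropped with a warning.
    """
    known = set(genes["seqid"])
    unknown = hits[~hits["seqid"].isin(known)]
    if len(unknown):
        warnings.warn(
            f"dropping {len(unknown)} hits on sequences without genes",
            stacklevel=2,
        )
    rows = []
    by_seq = {s: g for s, g in genes.groupby("seqid")}
    for _, h in hits.iterrows():
        g = by_seq.get(h["seqid"])
        if g is None:
            continue
        contained = g[
            (g["start"] - flank <= h["start"]) & (h["end"] <= g["end"] + flank)
        ]
        if len(contained) == 0:
            row = dict(h)
            row.update(gene_id=None, orientation="none", focal=False)
            rows.append(row)
            continue
        for _, gr in contained.iterrows():
            row = dict(h)
            row.update(
                gene_id=gr["gene_id"],
                orientation=(
                    "sense" if gr["strand"] == h["strand"] else "antisense"
                ),
                focal=bool(gr.get("focal", False)),
            )
            rows.append(row)
    cols = list(hits.columns) + ["gene_id", "orientation", "focal"]
    return pd.DataFrame(rows, columns=cols)


def hit_enrichment(
    assigned_hits: pd.DataFrame,
    focal_genes: Iterable,
    universe_genes: Iterable,
    n_resample: int = 999,
    seed: int = 0,
    count_mode: str = "hits",
) -> dict:
    """Over-representation of hits inside a focal gene set, by resampling.

    ``observed`` counts hits (or distinct host genes, with
    ``count_mode='genes'``) hosted by focal genes; the null redraws gene
    sets of the same size uniformly from the universe;
    ``p = (1 + #{null >= observed}) / (n_resample + 1)``.
    """
    focal = set(focal_genes)
    universe = sorted(set(universe_genes))
    if not focal <= set(universe):
        raise ValueError("focal genes must be a subset of the universe")
    hosted = assigned_hits[assigned_hits["gene_id"].notna()]
    if count_mode == "hits":
        per_gene = hosted.groupby("gene_id").size()
    elif count_mode == "genes":
        per_gene = (
            hosted.groupby("gene_id")["query_id"].nunique().clip(upper=1)
        )
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    counts = np.array([per_gene.get(g, 0) for g in universe], dtype=float)
    focal_mask = np.array([g in focal for g in universe])
    observed = float(counts[focal_mask].sum())

    rng = np.random.default_rng(seed)
    k = int(focal_mask.sum())
    null = np.empty(n_resample)
    for i in range(n_resample):
        idx = rng.choice(len(universe), size=k, replace=False)
        null[i] = counts[idx].sum()
    p = (1.0 + np.sum(null >= observed)) / (n_resample + 1.0)
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "p": float(p),
        "n_resample": n_resample,
    }
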