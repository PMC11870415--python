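"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV tables, BED intervals (0-based half-open),
MatrixMarket sparse counts and a JSON truth record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_simulation(outdir, cells, peak_counts, gene_counts, annotation,
                     truth, reads=None, footprints=None, spatial=None) -> None:
    """Write a simulated dataset in the pipeline's exchange formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    annotation["peaks"].to_csv(out / "peaks.bed", sep="\t", index=False,
                               header=False,
                               columns=["chrom", "start", "end", "peak_id"])
    spio.mmwrite(out / "counts_peaks.mtx", sparse.coo_matrix(peak_counts))
    spio.mmwrite(out / "counts_genes.mtx", sparse.coo_matrix(gene_counts))
    fam = pd.DataFrame({"family_id": annotation["family_ids"]})
    fam.to_csv(out / "families.tsv", sep="\t", index=False)
    pd.DataFrame(annotation["gene_programs"],
                 index=annotation["family_ids"],
                 columns=annotation["gene_ids"]).to_csv(
        out / "gene_programs.tsv", sep="\t")
    if reads is not None:
        reads.to_csv(out / "barcode_reads.tsv", sep="\t", index=False)
    if footprints is not None:
        footprints.to_csv(out / "footprints.tsv", sep="\t", index=False)
    if spatial is not None:
        bins, counts = spatial
        bins.to_csv(out / "spatial_bins.tsv", sep="\t", index=False)
        spio.mmwrite(out / "counts_spatial.mtx", sparse.coo_matrix(counts))
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray)
            else v.to_dict(orient="list") if isinstance(v, pd.DataFrame)
            else v)
        for k, v in truth.items() if k != "latent_scores"}
    (out / "truth.json").write_text(json.dumps(serializable, default=str))


def read_counts_mtx(path) -> sparse.csr_matrix:
    return sparse.csr_matrix(spio.mmread(path))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "peak_id"])
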