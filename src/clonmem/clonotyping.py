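"""Clonal-barcode read parsing and edit-distance consensus clone calling.

Reads carry a 7-bp anchor (``TAGACAT``) followed by a 48-bp expressed clonal
barcode whose structure is eight blocks of four random bases each followed by
an invariant dinucleotide (CT, AC, TC, GT, TG, CA, AT, GC at 0-based offsets
4, 10, 16, 22, 28, 34, 40, 46).  Parsing locates the leftmost 7-mer within
Hamming distance 1 of the anchor, trims it and everything 5' of it, validates
the invariant structure of the next 48 bp and discards PCR artifacts
(all-G UMIs, broken anchors, truncated reads).

Clone calling is two-step agglomeration on the Levenshtein distance matrix of
the retained 48-mers: each barcode is assigned to the most abundant barcode
within distance ``d1`` (default 4) of it, and the resulting assigned-to set
is collapsed once more at distance ``d2`` (default 2), always toward the
more abundant member.  Abundance ties break toward the lexicographically
smaller sequence so the procedure is order-independent.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import ANCHOR, BARCODE_LENGTH, INVARIANT_DINUCLEOTIDES, INVARIANT_OFFSETS

__all__ = [
    "parse_barcode_read", "parse_barcode_reads", "count_and_filter_triples",
    "call_clone_consensus", "assign_clones", "CloneCaller",
]


def _find_anchor(seq: str, anchor: str = ANCHOR, max_mismatch: int = 1) -> int:
    """Index of the leftmost occurrence of ``anchor`` within Hamming distance
    ``max_mismatch``, or -1."""
    k = len(anchor)
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        mm = 0
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return -1


def parse_barcode_read(read_sequence: str, umi: str, *, anchor: str = ANCHOR,
                       max_mismatch: int = 1, validate: bool = True):
    """Extract the 48-bp clonal barcode from one read.

    Returns ``(barcode48, None)`` on success or ``(None, reason)`` where
    reason is one of ``umi_all_G``, ``no_anchor``, ``truncated``,
    ``invariant_mismatch``.
    """
    if set(umi) == {"G"}:
        return None, "umi_all_G"
    pos = _find_anchor(read_sequence, anchor, max_mismatch)
    if pos < 0:
        return None, "no_anchor"
    start = pos + len(anchor)
    barcode = read_sequence[start:start + BARCODE_LENGTH]
    if len(barcode) < BARCODE_LENGTH:
        return None, "truncated"
    if validate:
        for off, dinuc in zip(INVARIANT_OFFSETS, INVARIANT_DINUCLEOTIDES):
            if barcode[off:off + 2] != dinuc:
                return None, "invariant_mismatch"
    return barcode, None


def parse_barcode_reads(reads: pd.DataFrame, *, anchor: str = ANCHOR,
                        max_mismatch: int = 1,
                        validate: bool = True) -> pd.DataFrame:
    """Parse a BarcodeReadTable (cell_barcode, umi, read_sequence).

    Returns a DataFrame with columns cell_barcode, umi, barcode48, reject —
    one row per input read; rejected reads have barcode48 NA and a reason.
    """
    barcodes, reasons = [], []
    for seq, umi in zip(reads["read_sequence"], reads["umi"]):
        bc, reason = parse_barcode_read(seq, umi, anchor=anchor,
                                        max_mismatch=max_mismatch,
                                        validate=validate)
        barcodes.append(bc)
        reasons.append(reason)
    out = reads[["cell_barcode", "umi"]].copy()
    out["barcode48"] = barcodes
    out["reject"] = reasons
    return out


def count_and_filter_triples(parsed: pd.DataFrame,
                             min_reads: int = 5) -> pd.DataFrame:
    """Count reads per (cell_barcode, umi, barcode48) triple, dropping
    rejected reads and triples supported by fewer than ``min_reads`` reads."""
    ok = parsed.dropna(subset=["barcode48"])
    if len(ok) == 0:
        return pd.DataFrame(columns=["cell_barcode", "umi", "barcode48",
                                     "read_count"])
    counts = (ok.groupby(["cell_barcode", "umi", "barcode48"], sort=True)
                .size().rename("read_count").reset_index())
    return counts[counts["read_count"] >= min_reads].reset_index(drop=True)


def _levenshtein_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + 1, n):
            dist = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            d[i, j] = d[j, i] = dist
    return d


def call_clone_consensus(abundances: dict[str, int], d1: int = 4,
                         d2: int = 2):
    """Two-step consensus clustering of barcode sequences by edit distance.

    ``abundances`` maps each retained 48-mer to its total read count.
    Step 1 assigns every sequence to the most abundant sequence within
    Levenshtein distance ``d1`` of it (a sequence's own neighborhood includes
    itself).  Step 2 recomputes distances among the assigned-to sequences and
    collapses any within distance ``d2`` to the more abundant member,
    processed in descending abundance so chains resolve toward the globally
    most abundant sequence.  Ties in abundance break toward the
    lexicographically smaller sequence.

    Returns ``(consensus, mapping)``: the sorted consensus list and the
    composed barcode -> consensus map covering every input sequence.
    """
    if not abundances:
        raise ValueError("empty abundance map")
    seqs = sorted(abundances)                # lexicographic ties resolved here
    counts = np.array([abundances[s] for s in seqs])
    dist = _levenshtein_matrix(seqs)

    # step 1: assign to the most abundant neighbor within d1
    step1 = {}
    for i, s in enumerate(seqs):
        nbrs = np.flatnonzero(dist[i] <= d1)
        best = nbrs[np.argmax(counts[nbrs])]  # argmax takes first on tie ->
        step1[s] = seqs[best]                 # lexicographically smaller seq

    # step 2: collapse assigned-to set at d2, descending abundance
    targets = sorted(set(step1.values()))
    t_counts = np.array([abundances[t] for t in targets])
    t_dist = _levenshtein_matrix(targets)
    order = sorted(range(len(targets)), key=lambda i: (-t_counts[i], targets[i]))
    step2 = {}
    consensus: list[str] = []
    for i in order:
        t = targets[i]
        merged = False
        for c in consensus:
            if t_dist[i, targets.index(c)] <= d2:
                step2[t] = c
                merged = True
                break
        if not merged:
            step2[t] = t
            consensus.append(t)

    mapping = {s: step2[step1[s]] for s in seqs}
    return sorted(consensus), mapping


def assign_clones(mapping: dict[str, str], triples: pd.DataFrame,
                  cell_samples: pd.Series | dict, min_cells: int = 5):
    """Assign cells to clones and clones to samples.

    Each cell takes the clone supported by the plurality of its retained
    UMIs (a UMI votes for the consensus its barcode maps to); ties leave the
    cell unassigned.  Each clone is then assigned to the sample contributing
    the most member cells, cells from other samples are dropped from the
    clone (cross-sample transcript mixing), and clones with fewer than
    ``min_cells`` remaining cells are removed.

    Returns a dict with consensus_barcodes, cell_to_clone, clone_to_sample,
    clone_sizes and the list of tie-unassigned cells.
    """
    if isinstance(cell_samples, dict):
        cell_samples = pd.Series(cell_samples)

    t = triples.copy()
    t["consensus"] = t["barcode48"].map(mapping)
    t = t.dropna(subset=["consensus"])
    # UMI votes: one vote per (cell, umi) pair for its consensus
    votes = (t.drop_duplicates(["cell_barcode", "umi", "consensus"])
              .groupby(["cell_barcode", "consensus"]).size()
              .rename("n_umis").reset_index())

    cell_to_clone: dict[str, str] = {}
    unassigned: list[str] = []
    for cell, grp in votes.groupby("cell_barcode"):
        top = grp["n_umis"].max()
        winners = grp.loc[grp["n_umis"] == top, "consensus"]
        if len(winners) == 1:
            cell_to_clone[cell] = winners.iloc[0]
        else:
            unassigned.append(cell)

    # clone -> sample by plurality of member cells
    members = pd.DataFrame({"cell": list(cell_to_clone),
                            "clone": list(cell_to_clone.values())})
    members["sample"] = members["cell"].map(cell_samples)
    clone_to_sample: dict[str, str] = {}
    for clone, grp in members.groupby("clone"):
        tally = Counter(grp["sample"])
        top = max(tally.values())
        clone_to_sample[clone] = sorted(
            s for s, c in tally.items() if c == top)[0]

    # drop cross-sample cells, then undersized clones
    keep = members[members.apply(
        lambda r: clone_to_sample[r["clone"]] == r["sample"], axis=1)]
    sizes = keep.groupby("clone").size()
    valid = set(sizes[sizes >= min_cells].index)
    keep = keep[keep["clone"].isin(valid)]

    return {
        "consensus_barcodes": sorted(valid),
        "cell_to_clone": dict(zip(keep["cell"], keep["clone"])),
        "clone_to_sample": {c: clone_to_sample[c] for c in sorted(valid)},
        "clone_sizes": keep.groupby("clone").size().to_dict(),
        "unassigned_cells": unassigned,
    }


class CloneCaller(BaseEstimator):
    """End-to-end clone calling from a barcode read table.

    Parameters follow the published procedure: reads are parsed against the
    TAGACAT anchor (``max_mismatch`` 1), cell-UMI-barcode triples with fewer
    than ``min_reads`` reads are dropped, consensus clustering runs at
    distances ``d1``/``d2``, and clones with fewer than ``min_cells`` cells
    are removed.

    Attributes (after :meth:`fit`)
    ------------------------------
    consensus_barcodes_ : list of retained consensus 48-mers
    cell_to_clone_ : dict cell_barcode -> consensus
    clone_to_sample_ : dict consensus -> sample
    clone_sizes_ : dict consensus -> member cell count
    unassigned_cells_ : cells with a UMI-vote tie
    barcode_mapping_ : raw barcode -> consensus map (before size filtering)
    """

    def __init__(self, min_reads: int = 5, min_cells: int = 5, d1: int = 4,
                 d2: int = 2, anchor: str = ANCHOR, max_mismatch: int = 1):
        self.min_reads = min_reads
        self.min_cells = min_cells
        self.d1 = d1
        self.d2 = d2
        self.anchor = anchor
        self.max_mismatch = max_mismatch

    def fit(self, reads: pd.DataFrame, cell_samples: pd.Series | dict):
        """Parse, filter, cluster and assign; ``cell_samples`` maps
        cell_barcode -> sample."""
        parsed = parse_barcode_reads(reads, anchor=self.anchor,
                                     max_mismatch=self.max_mismatch)
        triples = count_and_filter_triples(parsed, min_reads=self.min_reads)
        if len(triples) == 0:
            raise ValueError("no triples survive the read-count filter")
        abundances = (triples.groupby("barcode48")["read_count"].sum()
                      .to_dict())
        consensus, mapping = call_clone_consensus(abundances, d1=self.d1,
                                                  d2=self.d2)
        self.barcode_mapping_ = mapping
        result = assign_clones(mapping, triples, cell_samples,
                               min_cells=self.min_cells)
        self.consensus_barcodes_ = result["consensus_barcodes"]
        self.cell_to_clone_ = result["cell_to_clone"]
        self.clone_to_sample_ = result["clone_to_sample"]
        self.clone_sizes_ = result["clone_sizes"]
        self.unassigned_cells_ = result["unassigned_cells"]
        self.n_rejected_reads_ = int(parsed["barcode48"].isna().sum())
        return self

    def assignment_frame(self) -> pd.DataFrame:
        """cell_clones table: cell_barcode, clone (consensus), sample."""
        return pd.DataFrame({
            "cell_barcode": list(self.cell_to_clone_),
            "clone": list(self.cell_to_clone_.values()),
            "sample": [self.clone_to_sample_[c]
                       for c in self.cell_to_clone_.values()],
        })
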