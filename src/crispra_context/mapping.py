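"""Barcode genotyping: read filtering, location consolidation and
two-enzyme reconciliation.

Inverse-PCR reads carry a fixed structure (piggyBac/upstream anchor,
17-nt barcode, downstream anchor, genomic flank).  Reads failing the
structure are tallied by rejection reason.  Per-barcode candidate
locations within 10 bp of each other are merged (counts summed, midpoint
position); a barcode whose merged candidates still span multiple
locations is flagged ambiguous and excluded downstream.  Barcodes mapped
by at least one of the two restriction enzymes are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import UPSTREAM_ANCHOR, DOWNSTREAM_ANCHOR
from .genome import GenomeContext
from .simulate import revcomp

MERGE_DISTANCE = 10  # bp: max pairwise distance merged into one location


@dataclass
class ReadStructureSpec:
    upstream_anchor: str = UPSTREAM_ANCHOR
    downstream_anchor: str = DOWNSTREAM_ANCHOR
    barcode_length: int = 17
    max_anchor_mismatches: int = 1
    min_flank_length: int = 20

    def __post_init__(self):
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be non-empty")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be > 0")


@dataclass
class MappedBarcode:
    barcode: str
    chrom: str | None
    position: int | None
    read_count: int
    ambiguous: bool
    enzymes: set = field(default_factory=set)
    support_class: str = "single_enzyme"


def _find_anchor(seq: str, anchor: str, start: int, max_mm: int) -> int:
    """Leftmost position >= start where anchor matches with <= max_mm
    mismatches; -1 if none."""
    idx = seq.find(anchor, start)
    if idx >= 0 or max_mm == 0:
        return idx
    la = len(anchor)
    for i in range(start, len(seq) - la + 1):
        mm = 0
        for a, b in zip(anchor, seq[i:i + la]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def extract_barcodes(reads, spec: ReadStructureSpec):
    """Filter reads to the declared structure.

    Parameters
    ----------
    reads : iterable of (read_id, sequence)
    spec : ReadStructureSpec

    Returns
    -------
    records : list of (read_id, barcode, flank)
    tally : dict counting rejects by reason
    """
    records = []
    tally = {"accepted": 0, "no_upstream_anchor": 0,
             "no_downstream_anchor": 0, "barcode_length": 0, "short_flank": 0}
    for rid, seq in reads:
        up = _find_anchor(seq, spec.upstream_anchor, 0,
                          spec.max_anchor_mismatches)
        if up < 0:
            tally["no_upstream_anchor"] += 1
            continue
        bc_start = up + len(spec.upstream_anchor)
        down = _find_anchor(seq, spec.downstream_anchor, bc_start,
                            spec.max_anchor_mismatches)
        if down < 0:
            tally["no_downstream_anchor"] += 1
            continue
        if down - bc_start != spec.barcode_length:
            tally["barcode_length"] += 1
            continue
        flank = seq[down + len(spec.downstream_anchor):]
        if len(flank) < spec.min_flank_length:
            tally["short_flank"] += 1
            continue
        tally["accepted"] += 1
        records.append((rid, seq[bc_start:down], flank))
    return records, tally


def map_flanks_exact(records, genome: GenomeContext) -> pd.DataFrame:
    """Exact substring search of flanks against the synthetic genome.

    Returns candidate locations per barcode: (barcode, chrom, pos,
    read_count).  The reported position is the insertion site: the flank
    start for forward hits, the flank end for reverse-complement hits.
    On real data a pre-aligned table replaces this step.
    """
    counts: dict[tuple, int] = {}
    flank_cache: dict[str, tuple] = {}
    for _, barcode, flank in records:
        if flank not in flank_cache:
            hit = None
            for chrom, seq in genome.sequences.items():
                idx = seq.find(flank)
                if idx >= 0:
                    hit = (chrom, idx)
                    break
                idx = seq.find(revcomp(flank))
                if idx >= 0:
                    hit = (chrom, idx + len(flank))
                    break
            flank_cache[flank] = hit
        hit = flank_cache[flank]
        if hit is None:
            continue
        key = (barcode, hit[0], hit[1])
        counts[key] = counts.get(key, 0) + 1
    rows = [(b, c, p, n) for (b, c, p), n in counts.items()]
    return pd.DataFrame(rows, columns=["barcode", "chrom", "pos",
                                       "read_count"])


def single_linkage_clusters(positions: np.ndarray,
                            threshold: int = MERGE_DISTANCE) -> np.ndarray:
    """Cluster ids for sorted-order single-linkage at the given distance."""
    order = np.argsort(positions, kind="stable")
    labels = np.empty(len(positions), dtype=int)
    cluster = 0
    prev = None
    for i in order:
        if prev is not None and positions[i] - prev > threshold:
            cluster += 1
        labels[i] = cluster
        prev = positions[i]
    return labels


def consolidate_locations(candidates) -> MappedBarcode:
    """Merge a barcode's candidate locations that lie within 10 bp.

    ``candidates`` is a list of (chrom, pos, read_count) sharing one
    barcode (the barcode itself is carried by the caller).  Same-
    chromosome candidates are merged by single linkage at 10 bp; the
    merged position is the midpoint of the cluster span (rounded toward
    zero) and counts are summed.  More than one surviving cluster means
    the barcode is ambiguous.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    clusters = []
    df = pd.DataFrame(candidates, columns=["chrom", "pos", "count"])
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp.pos.to_numpy()
        labels = single_linkage_clusters(pos)
        for lab in np.unique(labels):
            sel = labels == lab
            span_lo, span_hi = pos[sel].min(), pos[sel].max()
            clusters.append((chrom, int((span_lo + span_hi) // 2),
                             int(grp["count"].to_numpy()[sel].sum())))
    total = sum(c[2] for c in clusters)
    if len(clusters) > 1:
        return MappedBarcode(barcode="", chrom=None, position=None,
                             read_count=total, ambiguous=True)
    chrom, mid, cnt = clusters[0]
    return MappedBarcode(barcode="", chrom=chrom, position=mid,
                         read_count=cnt, ambiguous=False)


def consolidate_all(candidates: pd.DataFrame, enzyme: str
                    ) -> dict[str, MappedBarcode]:
    """Apply :func:`consolidate_locations` to every barcode in a candidate
    table (columns barcode, chrom, pos, read_count)."""
    out = {}
    for barcode, grp in candidates.groupby("barcode"):
        mb = consolidate_locations(
            list(zip(grp.chrom, grp.pos, grp.read_count)))
        mb.barcode = barcode
        mb.enzymes = {enzyme}
        out[barcode] = mb
    return out


def reconcile_enzymes(tat: dict[str, MappedBarcode],
                      msp: dict[str, MappedBarcode]):
    """Combine per-enzyme mappings into the final pool.

    Barcodes unambiguous in both enzymes and agreeing within 10 bp get
    support class "both" with a read-count-weighted midpoint position;
    barcodes mapped by exactly one enzyme are "single_enzyme"; cross-
    enzyme disagreement or ambiguity in the only supporting enzyme makes
    the barcode "ambiguous" (excluded downstream).

    Returns
    -------
    pool : DataFrame (barcode, chrom, pos, read_count, support_class)
        Rows only for usable (non-ambiguous) barcodes.
    summary : dict with the fraction of barcodes per support class.
    """
    rows = []
    n_by_class = {"both": 0, "single_enzyme": 0, "ambiguous": 0}
    for barcode in sorted(set(tat) | set(msp)):
        a, b = tat.get(barcode), msp.get(barcode)
        if a is not None and b is not None:
            if a.ambiguous or b.ambiguous:
                # fall back to the unambiguous enzyme if there is one
                good = [m for m in (a, b) if not m.ambiguous]
                if len(good) == 1:
                    m = good[0]
                    n_by_class["single_enzyme"] += 1
                    rows.append((barcode, m.chrom, m.position, m.read_count,
                                 "single_enzyme"))
                else:
                    n_by_class["ambiguous"] += 1
                continue
            if (a.chrom == b.chrom
                    and abs(a.position - b.position) <= MERGE_DISTANCE):
                wa, wb = a.read_count, b.read_count
                pos = int((a.position * wa + b.position * wb) // (wa + wb))
                n_by_class["both"] += 1
                rows.append((barcode, a.chrom, pos, wa + wb, "both"))
            else:
                n_by_class["ambiguous"] += 1
        else:
            m = a if a is not None else b
            if m.ambiguous:
                n_by_class["ambiguous"] += 1
            else:
                n_by_class["single_enzyme"] += 1
                rows.append((barcode, m.chrom, m.position, m.read_count,
                             "single_enzyme"))
    pool = pd.DataFrame(rows, columns=["barcode", "chrom", "pos",
                                       "read_count", "support_class"])
    total = max(sum(n_by_class.values()), 1)
    summary = {f"frac_{k}": v / total for k, v in n_by_class.items()}
    summary["n_total"] = total
    summary["n_mapped"] = len(pool)
    return pool, summary


def map_reads(reads_by_enzyme: dict, genome: GenomeContext,
              spec: ReadStructureSpec | None = None):
    """End-to-end genotyping: extract, map, consolidate, reconcile."""
    spec = spec or ReadStructureSpec()
    per_enzyme = {}
    tallies = {}
    for enzyme, reads in reads_by_enzyme.items():
        records, tally = extract_barcodes(reads, spec)
        candidates = map_flanks_exact(records, genome)
        per_enzyme[enzyme] = consolidate_all(candidates, enzyme)
        tallies[enzyme] = tally
    enzymes = list(reads_by_enzyme)
    pool, summary = reconcile_enzymes(per_enzyme[enzymes[0]],
                                      per_enzyme[enzymes[1]])
    summary["read_tallies"] = tallies
    return pool, summary
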