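"""Enumerate every cytosine on both strands and assign its methylation context.

Plant methylomes distinguish three sequence contexts by the two bases 3' of
each cytosine on its own strand: CG, CHG and CHH (H = A, C or T). A
plus-strand C at position *i* reads its context from positions i+1, i+2; a
plus-strand G is a minus-strand C whose trinucleotide is the reverse
complement of the plus-strand bases at [i-2, i]. Trinucleotides truncated by
a contig end or containing N get context "unknown" and are excluded by all
downstream statistics.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "tri"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _context_codes(b2: np.ndarray, b3: np.ndarray) -> np.ndarray:
    """Context from the 2nd/3rd trinucleotide bases (uint8 ASCII arrays).

    A trinucleotide truncated by the contig end or containing N is always
    "unknown", even when the known bases would suffice to call the context.
    """
    G, N = ord("G"), ord("N")
    known2 = (b2 != N) & (b2 != 0)
    known3 = (b3 != N) & (b3 != 0)
    known = known2 & known3
    h2 = known & (b2 != G)
    ctx = np.full(b2.shape, "unknown", dtype=object)
    ctx[known & (b2 == G)] = "CG"
    ctx[h2 & (b3 == G)] = "CHG"
    ctx[h2 & (b3 != G)] = "CHH"
    return ctx


def extract_cytosine_contexts(genome: Mapping[str, str]) -> pd.DataFrame:
    """Site table for every C (plus strand) and G (minus-strand C).

    Returns a frame with columns (chrom, pos, strand, context, tri) sorted by
    (chrom, pos, strand); ``pos`` is 0-based and refers to the plus strand.
    """
    frames = []
    for chrom in genome:
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n = arr.size
        C, G = ord("C"), ord("G")

        # shifted base arrays; 0 marks "off the end of the contig"
        def shifted(offset: int) -> np.ndarray:
            out = np.zeros(n, dtype=np.uint8)
            if offset > 0:
                out[: n - offset] = arr[offset:]
            elif offset < 0:
                out[-offset:] = arr[:offset]
            else:
                out[:] = arr
            return out

        comp = arr.copy()
        for a, b in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
            comp[arr == ord(a)] = ord(b)
        comp[arr == ord("N")] = ord("N")

        def comp_shifted(offset: int) -> np.ndarray:
            out = np.zeros(n, dtype=np.uint8)
            if offset > 0:
                out[: n - offset] = comp[offset:]
            elif offset < 0:
                out[-offset:] = comp[:offset]
            else:
                out[:] = comp
            return out

        plus = np.flatnonzero(arr == C)
        minus = np.flatnonzero(arr == G)

        ctx_plus = _context_codes(shifted(1)[plus], shifted(2)[plus])
        ctx_minus = _context_codes(comp_shifted(-1)[minus], comp_shifted(-2)[minus])

        tri_plus = [seq[i:i + 3] if i + 3 <= n else seq[i:] for i in plus]
        tri_minus = [revcomp(seq[max(0, i - 2):i + 1]) for i in minus]

        sub = pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([plus, minus]).astype(np.int64),
            "strand": ["+"] * plus.size + ["-"] * minus.size,
            "context": np.concatenate([ctx_plus, ctx_minus]),
            "tri": tri_plus + tri_minus,
        })
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return sites.reset_index(drop=True)


def validate_cx_contexts(sample: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Positions where a CX report's context disagrees with the genome.

    Returns a frame (chrom, pos, strand, kind, report_context, genome_context)
    with kind ``mismatch`` for disagreeing contexts and ``missing`` for report
    positions absent from the genome-derived site table.
    """
    merged = sample.merge(
        sites, on=["chrom", "pos", "strand"], how="left",
        suffixes=("_report", "_genome"))
    missing = merged["context_genome"].isna()
    mismatch = ~missing & (merged["context_report"] != merged["context_genome"])
    out = merged.loc[missing | mismatch,
                     ["chrom", "pos", "strand",
                      "context_report", "context_genome"]].copy()
    out["kind"] = np.where(
        out["context_genome"].isna(), "missing", "mismatch")
    return out.reset_index(drop=True)
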