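"""Promoter scanning for IUPAC cis-elements and preferentially located motifs.

A preferentially located motif (PLM) is a motif whose occurrences pile up
in a specific window of positions relative to the transcription start
site.  Promoters are fixed-length sequences covering positions
``-L .. -1`` upstream of the TSS; an occurrence is anchored at the match
base closest to the TSS.  Detection bins the anchor positions, tests each
bin against a uniform null, and takes the maximal run of significant bins
as the functional window.  Cluster-level over-representation of a PLM is
then a one-sided binomial test of the cluster's hit count against the
genome-wide hit proportion inside that window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: IUPAC nucleotide codes (N matches any base; promoter 'N's match only N
#: patterns under exact-base semantics, see `_char_class`).
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PromoterSet(dict):
    """gene_id -> promoter sequence, all of one length, alphabet ACGTN."""

    def __init__(self, sequences: Mapping[str, str]):
        sequences = {g: s.upper() for g, s in sequences.items()}
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"promoters have mixed lengths: {sorted(lengths)}")
        for g, s in sequences.items():
            extra = set(s) - set("ACGTN")
            if extra:
                raise ValueError(f"promoter {g} has letters outside ACGTN: {sorted(extra)}")
        super().__init__(sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.values()))) if self else 0

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        from ._io import read_fasta

        return cls(read_fasta(path))

    def to_fasta(self, path) -> None:
        from ._io import write_fasta

        write_fasta(self, path)


@dataclass(frozen=True)
class PLMRecord:
    """A motif with a detected functional window and its genome background."""

    motif_id: str
    window: tuple[int, int]  # closed interval of TSS-relative positions
    genome_genes_with_hit_in_window: int
    genome_total: int
    pvalue: float

    @property
    def background_proportion(self) -> float:
        return self.genome_genes_with_hit_in_window / self.genome_total


@dataclass(frozen=True)
class MotifEnrichmentResult:
    cluster_id: str
    motif_id: str
    k: int
    n: int
    p0: float
    pvalue: float
    significant: bool


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _char_class(code: str) -> str:
    bases = IUPAC_CODES[code]
    return bases if len(bases) == 1 else f"[{bases}]"


def _compile(motif: str) -> re.Pattern:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC letters in motif {motif!r}: {sorted(bad)}")
    # Lookahead so that overlapping matches are all reported.
    return re.compile("(?=" + "".join(_char_class(c) for c in motif) + ")")


def scan_motif(
    promoters: Mapping[str, str],
    motif: str,
    strands: str = "both",
) -> dict[str, list[int]]:
    """All exact IUPAC matches of ``motif``, as TSS-relative anchor positions.

    The anchor is the match base closest to the TSS (position ``-1`` abuts
    the TSS).  With ``strands="both"`` a reverse-complement match is
    reported at the forward-strand window it occupies; a window matched on
    both strands counts once.
    """
    if strands not in ("given", "both"):
        raise ValueError("strands must be 'given' or 'both'")
    patterns = [_compile(motif)]
    if strands == "both":
        rc = reverse_complement(motif)
        if rc.upper() != motif.upper():
            patterns.append(_compile(rc))
    m = len(motif)
    out: dict[str, list[int]] = {}
    for gene, seq in promoters.items():
        L = len(seq)
        starts: set[int] = set()
        for pat in patterns:
            starts.update(match.start() for match in pat.finditer(seq))
        # start index i occupies i..i+m-1; anchor = rightmost base.
        out[gene] = sorted(i - L + m - 1 for i in starts if i + m <= L)
    return out


def scan_catalog(
    promoters: Mapping[str, str],
    catalog: pd.DataFrame,
    strands: str = "both",
) -> pd.DataFrame:
    """Scan every catalog motif; returns a BED-like table of occurrences.

    ``catalog`` needs columns ``motif_id`` and ``iupac``.  Output columns:
    gene_id, start, end (TSS-relative closed interval), motif_id.
    """
    rows = []
    for _, rec in catalog.iterrows():
        m = len(rec["iupac"])
        hits = scan_motif(promoters, rec["iupac"], strands=strands)
        for gene, anchors in hits.items():
            for anchor in anchors:
                rows.append(
                    {"gene_id": gene, "start": anchor - m + 1, "end": anchor, "motif_id": rec["motif_id"]}
                )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "motif_id"])


def detect_plm(
    occurrences: Mapping[str, Iterable[int]],
    promoter_length: int = 1000,
    bin_width: int = 50,
    alpha_detect: float = 0.01,
    motif_id: str = "",
) -> PLMRecord | None:
    """Detect a preferential window from genome-wide anchor positions.

    Anchor positions are binned at ``bin_width``; each bin's gene count
    (a gene counts once per bin) is tested one-sided against the uniform
    expectation ``Binomial(G, 1/n_bins)`` where G is the number of genes
    with any occurrence.  Bins significant at ``alpha_detect`` after
    Bonferroni correction over bins form candidate runs; the maximal run
    of contiguous significant bins is the functional window.  Returns
    ``None`` when no bin is significant (the motif is not a PLM).
    """
    n_bins = promoter_length // bin_width
    genes_with_hit = [g for g, pos in occurrences.items() if len(list(pos)) > 0]
    G = len(genes_with_hit)
    if G == 0:
        return None
    counts = np.zeros(n_bins, dtype=int)
    for g in genes_with_hit:
        bins = {(p + promoter_length) // bin_width for p in occurrences[g]}
        for b in bins:
            if 0 <= b < n_bins:
                counts[b] += 1
    pvals = stats.binom.sf(counts - 1, G, 1.0 / n_bins)
    significant = pvals < alpha_detect / n_bins
    if not significant.any():
        return None
    # maximal run of contiguous significant bins; ties broken by smallest p
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(significant):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n_bins - 1))
    best = max(runs, key=lambda r: (r[1] - r[0], -pvals[r[0] : r[1] + 1].min()))
    a = -promoter_length + best[0] * bin_width
    b = -promoter_length + (best[1] + 1) * bin_width - 1
    in_window = sum(
        1 for g in genes_with_hit if any(a <= p <= b for p in occurrences[g])
    )
    return PLMRecord(
        motif_id=motif_id,
        window=(a, b),
        genome_genes_with_hit_in_window=in_window,
        genome_total=len(occurrences),
        pvalue=float(pvals[significant].min()),
    )


def genes_with_hit_in_window(
    occurrences: Mapping[str, Iterable[int]], window: tuple[int, int]
) -> set[str]:
    a, b = window
    return {g for g, pos in occurrences.items() if any(a <= p <= b for p in pos)}


def test_cluster_enrichment(
    record: PLMRecord,
    cluster_genes: Iterable[str],
    occurrences: Mapping[str, Iterable[int]],
    alpha: float = 0.01,
    cluster_id: str = "",
) -> MotifEnrichmentResult:
    """Binomial over-representation of a PLM's window hits in a cluster.

    ``k`` counts cluster genes with at least one occurrence inside the
    functional window (a gene counts once however many matches it has);
    the p-value is the exact upper tail P(X >= k) for
    X ~ Binomial(n, p0) with p0 the genome-wide hit proportion.
    """
    cluster = set(cluster_genes)
    n = len(cluster)
    if n == 0:
        raise ValueError("cluster is empty")
    hits = genes_with_hit_in_window(occurrences, record.window)
    k = len(cluster & hits)
    p0 = record.background_proportion
    pvalue = float(stats.binom.sf(k - 1, n, p0))
    return MotifEnrichmentResult(
        cluster_id=cluster_id,
        motif_id=record.motif_id,
        k=k,
        n=n,
        p0=p0,
        pvalue=pvalue,
        significant=bool(pvalue < alpha),
    )


def find_plms(
    promoters: Mapping[str, str],
    catalog: pd.DataFrame,
    strands: str = "both",
    bin_width: int = 50,
    alpha_detect: float = 0.01,
) -> tuple[dict[str, PLMRecord], dict[str, dict[str, list[int]]]]:
    """Run the PLM detector over a whole motif catalog.

    Returns the detected records keyed by motif_id alongside the raw
    per-motif occurrence maps (needed for cluster enrichment).
    """
    length = len(next(iter(promoters.values())))
    records: dict[str, PLMRecord] = {}
    occ_by_motif: dict[str, dict[str, list[int]]] = {}
    for _, rec in catalog.iterrows():
        occ = scan_motif(promoters, rec["iupac"], strands=strands)
        occ_by_motif[rec["motif_id"]] = occ
        plm = detect_plm(
            occ,
            promoter_length=length,
            bin_width=bin_width,
            alpha_detect=alpha_detect,
            motif_id=rec["motif_id"],
        )
        if plm is not None:
            records[rec["motif_id"]] = plm
    return records, occ_by_motif
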