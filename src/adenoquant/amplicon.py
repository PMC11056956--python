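"""In-silico PCR utilities for the study's RT-qPCR primer panel.

The printed primer table renders each assay's forward and reverse
primers as one run-on string, so the split point is typographically
ambiguous; :func:`split_concatenated_primers` resolves it against the
reference transcript (the prefix must match the sense strand exactly
and the reverse-complement of the suffix must match downstream, both
uniquely). Product sizes are then computed by exact-match in-silico PCR.
Transcripts are supplied as FASTA files; nothing is fetched from the
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

_DNA = set("ACGT")


@dataclass(frozen=True)
class PrimerAssay:
    gene: str
    accession: str
    concatenated: str  # forward + reverse as printed, 5'->3' each
    expected_product_bp: int | None = None


# RT-qPCR panel: gene, reference transcript accession, run-on
# forward+reverse primer string, expected product size (bp)
PRIMER_ASSAYS = [
    PrimerAssay("Pgr", "NM_008829.2",
                "CTACTCGCTGTGCCTTACCATGCTGGCTTTGACTCCTCAGTCCT", 139),
    PrimerAssay("Hoxa10", "NM_008263.4",
                "GGCAGTTCCAAAGGCGAAAATGTCTGGTGCTTCGTGTAAGGC", 86),
    PrimerAssay("Itgb3", "NM_016780.2",
                "GGCGTTGTTGTTGGAGAGTCCTTCAGGTTACATCGGGGTCA", 138),
    PrimerAssay("Lif", "NM_008501.3",
                "GCTGTATCGGATGGTCGCATACACAGACGGCAAAGCACATT", 156),
    PrimerAssay("Gapdh", "NM_001289726.2",
                "GGTGGACCTCATGGCCTACACTCTCTTGATCAGTGTCCTTGCT", 82),
    PrimerAssay("Rplp0", "NM_007475.5",
                "GGACCCGAGAAGACCTCCTTGCACATCACTCAGAATTTCAATGG", 85),
]


class PrimerSplitError(ValueError):
    """Zero or multiple valid split points for a run-on primer string."""


class PCRSiteError(ValueError):
    """Missing, duplicated or mis-oriented primer binding sites."""


def _validate_dna(s: str, what: str) -> str:
    s = s.upper()
    if not s or set(s) - _DNA:
        raise ValueError(f"{what} must be non-empty A/C/G/T, got {s!r}")
    return s


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def split_concatenated_primers(
    concatenated: str, transcript: str, min_len: int = 15, max_len: int = 30
) -> tuple[str, str]:
    """Resolve a run-on forward+reverse primer string against a transcript.

    A split point is valid when the prefix occurs exactly once on the
    transcript sense strand and the reverse-complement of the suffix
    occurs exactly once downstream of it. Exactly one valid split must
    exist; otherwise a :class:`PrimerSplitError` lists the candidates.
    """
    s = _validate_dna(concatenated, "primer string")
    t = _validate_dna(transcript, "transcript")
    candidates: list[tuple[str, str]] = []
    lo = max(1, min_len)
    hi = min(len(s) - 1, len(s) - min_len) if min_len else len(s) - 1
    for i in range(lo, hi + 1):
        fwd, rev = s[:i], s[i:]
        if not (min_len <= len(fwd) <= max_len and min_len <= len(rev) <= max_len):
            continue
        fwd_hits = _find_all(t, fwd)
        if len(fwd_hits) != 1:
            continue
        site = str(Seq(rev).reverse_complement())
        rev_hits = [p for p in _find_all(t, site) if p > fwd_hits[0]]
        if len(rev_hits) != 1:
            continue
        candidates.append((fwd, rev))
    if len(candidates) != 1:
        raise PrimerSplitError(
            f"{len(candidates)} valid split(s) for {concatenated!r}: {candidates}"
        )
    return candidates[0]


def insilico_pcr(forward: str, reverse: str, transcript: str) -> int:
    """Exact-match PCR product length (bp), both primers included.

    The forward primer must bind the sense strand exactly once, the
    reverse primer (as its reverse complement) exactly once downstream;
    the product spans the forward 5' start through the reverse 5' start
    on the opposite strand.
    """
    fwd = _validate_dna(forward, "forward primer")
    rev = _validate_dna(reverse, "reverse primer")
    t = _validate_dna(transcript, "transcript")
    fwd_hits = _find_all(t, fwd)
    if len(fwd_hits) != 1:
        raise PCRSiteError(f"forward primer has {len(fwd_hits)} site(s)")
    site = str(Seq(rev).reverse_complement())
    rev_hits = _find_all(t, site)
    if len(rev_hits) != 1:
        raise PCRSiteError(f"reverse primer has {len(rev_hits)} site(s)")
    start = fwd_hits[0]
    end = rev_hits[0] + len(site)  # reverse primer 5' end on the sense strand
    if rev_hits[0] < start:
        raise PCRSiteError("reverse site lies upstream of the forward site")
    return end - start


def load_transcripts(fasta_path: str | Path) -> dict[str, str]:
    """Read a FASTA of reference transcripts keyed by record id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


def resolve_assays(
    transcripts: dict[str, str], assays: list[PrimerAssay] | None = None
):
    """Resolve each assay against its transcript; returns a list of dict
    rows (gene, accession, forward, reverse, product_bp, matches_expected)
    for the assays whose transcript is available."""
    rows = []
    for assay in assays if assays is not None else PRIMER_ASSAYS:
        seq = transcripts.get(assay.accession)
        if seq is None:
            continue
        fwd, rev = split_concatenated_primers(assay.concatenated, seq)
        size = insilico_pcr(fwd, rev, seq)
        rows.append(
            {
                "gene": assay.gene,
                "accession": assay.accession,
                "forward": fwd,
                "reverse": rev,
                "product_bp": size,
                "matches_expected": (
                    size == assay.expected_product_bp
                    if assay.expected_product_bp is not None else None
                ),
            }
        )
    return rows
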