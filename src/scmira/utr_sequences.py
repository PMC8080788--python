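"""3′UTR sequence handling.

miRNAs bind predominantly in 3′UTRs, so the gene universe of the activity
analysis is the set of genes with a usable 3′UTR sequence.  This module loads
UTR FASTA files, collapses multiple transcript isoforms to the longest UTR per
gene, applies the length filter (20–10,000 nt inclusive), and computes each
sequence's base composition — the quantity that, together with length,
parameterises the motif null probabilities.

An optional convenience path extracts 3′UTRs from a GENCODE-style GTF plus a
genome FASTA; the canonical input is a pre-built UTR FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from ._io import PathLike, open_text

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default header convention: ``>GENE|TRANSCRIPT ...`` (transcript optional).
DEFAULT_HEADER_REGEX = re.compile(r"^(?P<gene>[^|\s]+)(?:\|(?P<transcript>[^|\s]+))?")

_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class RawUtr:
    """One transcript's UTR as read from FASTA, before isoform collapsing."""

    gene_id: str
    transcript_id: str
    sequence: str
    flagged: bool  # True if characters outside {A,C,G,T,N} were present


@dataclass(frozen=True)
class UtrRecord:
    """One gene's chosen (longest-isoform) 3′UTR.

    ``base_freqs`` are the A,C,G,T frequencies among non-N positions; together
    with ``length`` they fully determine the motif occurrence probability for
    this gene, so the probability table is reproducible from the record alone.
    """

    gene_id: str
    sequence: str
    length: int
    base_freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(f"{self.gene_id}: length {self.length} != |sequence|")


def base_composition(sequence: str) -> np.ndarray:
    """A,C,G,T frequencies of ``sequence``, excluding N positions.

    Raises ``ValueError`` on an empty or all-N sequence.
    """
    if not sequence:
        raise ValueError("cannot compute base composition of empty sequence")
    counts = np.zeros(4, dtype=float)
    for ch in sequence:
        idx = _BASE_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return counts / total


def load_utr_fasta(
    source: Union[PathLike, IO[str]],
    header_regex: Union[str, re.Pattern, None] = None,
) -> list[RawUtr]:
    """Read a UTR FASTA into raw per-transcript records.

    Headers are parsed with ``header_regex`` (named groups ``gene`` and
    optionally ``transcript``); the default accepts ``gene|transcript``.
    Sequences are uppercased and U→T normalised.  Records containing
    characters outside {A,C,G,T,N} are kept but flagged.  An empty stream or
    a duplicate (gene, transcript) pair is an error.
    """
    if header_regex is None:
        header_regex = DEFAULT_HEADER_REGEX
    elif isinstance(header_regex, str):
        header_regex = re.compile(header_regex)

    handle = open_text(source)
    records: list[RawUtr] = []
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        m = header_regex.match(rec.description)
        if m is None:
            raise ValueError(f"FASTA header {rec.description!r} does not match header regex")
        gene = m.group("gene")
        transcript = (m.groupdict().get("transcript") or "") if m.groupdict() else ""
        key = (gene, transcript)
        if key in seen:
            raise ValueError(f"duplicate UTR record for (gene={gene!r}, transcript={transcript!r})")
        seen.add(key)
        seq = str(rec.seq).upper().replace("U", "T")
        flagged = not _VALID_CHARS.issuperset(seq)
        records.append(RawUtr(gene, transcript, seq, flagged))
    if not records:
        raise ValueError("empty UTR FASTA: no records found")
    return records


def select_longest_utr(raw_records: Iterable[RawUtr]) -> dict[str, UtrRecord]:
    """Collapse transcripts to one UTR per gene: the longest sequence.

    Length ties are broken by lexicographically smallest transcript_id so the
    choice is deterministic.  Idempotent: re-applying to its own output (one
    record per gene) returns the same records.
    """
    by_gene: dict[str, RawUtr] = {}
    for rec in raw_records:
        best = by_gene.get(rec.gene_id)
        if (
            best is None
            or len(rec.sequence) > len(best.sequence)
            or (len(rec.sequence) == len(best.sequence) and rec.transcript_id < best.transcript_id)
        ):
            by_gene[rec.gene_id] = rec
    out: dict[str, UtrRecord] = {}
    for gene_id in sorted(by_gene):
        rec = by_gene[gene_id]
        freqs = base_composition(rec.sequence)
        out[gene_id] = UtrRecord(
            gene_id=gene_id,
            sequence=rec.sequence,
            length=len(rec.sequence),
            base_freqs=tuple(freqs),
        )
    return out


def filter_by_length(
    records: dict[str, UtrRecord], min_len: int = 20, max_len: int = 10000
) -> dict[str, UtrRecord]:
    """Keep UTRs with min_len <= length <= max_len (both bounds inclusive)."""
    kept = {g: r for g, r in records.items() if min_len <= r.length <= max_len}
    removed = len(records) - len(kept)
    if removed:
        log.info("filter_by_length: removed %d of %d UTRs outside [%d, %d]",
                 removed, len(records), min_len, max_len)
    return kept


def write_utr_fasta(records: Iterable[Union[RawUtr, UtrRecord]], path: PathLike) -> None:
    with open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, RawUtr):
                header = f"{rec.gene_id}|{rec.transcript_id}" if rec.transcript_id else rec.gene_id
            else:
                header = rec.gene_id
            fh.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Optional: 3′UTR extraction from a GENCODE-dialect GTF + genome FASTA.
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def extract_utrs_from_gtf(gtf_path: PathLike, genome_fasta: PathLike) -> list[RawUtr]:
    """Extract per-transcript 3′UTR sequences from a GTF and genome FASTA.

    GENCODE conventions: 1-based inclusive coordinates; ``UTR`` features cover
    both ends, so the 3′ side is identified as the UTR segments strictly
    downstream (strand-aware) of the transcript's CDS.  Minus-strand UTRs are
    reverse-complemented so every returned sequence reads 5′→3′ on the mRNA.
    """
    import pyfaidx

    utr_segs: dict[tuple[str, str], list[tuple[str, int, int, str]]] = {}
    cds_span: dict[tuple[str, str], tuple[int, int]] = {}
    with open_text(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("UTR", "three_prime_utr", "CDS"):
                continue
            a = _parse_attributes(attrs)
            key = (a.get("gene_id", ""), a.get("transcript_id", ""))
            s, e = int(start), int(end)
            if feature == "CDS":
                lo, hi = cds_span.get(key, (s, e))
                cds_span[key] = (min(lo, s), max(hi, e))
            else:
                utr_segs.setdefault(key, []).append((chrom, s, e, strand))

    genome = pyfaidx.Fasta(str(genome_fasta))
    out: list[RawUtr] = []
    for key, segs in sorted(utr_segs.items()):
        strand = segs[0][3]
        span = cds_span.get(key)
        if span is not None:
            # three-prime side: downstream of the CDS on the coding strand
            if strand == "+":
                segs = [s for s in segs if s[1] > span[1]]
            else:
                segs = [s for s in segs if s[2] < span[0]]
        if not segs:
            continue
        segs.sort(key=lambda s: s[1])
        seq = "".join(str(genome[chrom][s - 1 : e]) for chrom, s, e, _ in segs).upper()
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        flagged = not _VALID_CHARS.issuperset(seq)
        out.append(RawUtr(gene_id=key[0], transcript_id=key[1], sequence=seq, flagged=flagged))
    return out
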