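"""Mature miRNA parsing, seed extraction and target-motif derivation.

The binding model is the canonical 7-nt seed: mature positions 2–8 from the
5′ end.  A gene is a putative target when its 3′UTR contains the seed's
reverse complement (read 5′→3′ in DNA), since miRNA:target pairing is
antiparallel.  miRNA families frequently share a seed, so identical target
motifs are deduplicated and scores broadcast back to every member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Union

from Bio import SeqIO

from ._io import PathLike, open_text

log = logging.getLogger(__name__)

_RNA_TO_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}

SEED_START = 1  # 0-based slice bounds for mature positions 2..8 (1-based)
SEED_END = 8


@dataclass(frozen=True)
class MirnaMotif:
    """A mature miRNA, its seed, and the DNA motif marking its target sites."""

    mirna_name: str
    mature_seq: str  # RNA alphabet
    seed: str  # 7-mer RNA, mature positions 2-8
    target_motif: str  # 7-mer DNA, reverse complement of the seed

    @classmethod
    def from_mature(cls, name: str, mature_seq: str) -> "MirnaMotif":
        mature = mature_seq.upper().replace("T", "U")
        seed = extract_seed(mature)
        return cls(
            mirna_name=name,
            mature_seq=mature,
            seed=seed,
            target_motif=seed_to_target_motif(seed),
        )


def parse_mirna_fasta(source: Union[PathLike, IO[str]]) -> list[tuple[str, str]]:
    """Read mature miRNA sequences from FASTA (miRBase dialect).

    Names are the first whitespace-delimited header token, preserved verbatim;
    sequences are uppercased and stored in the RNA alphabet (T→U).  Matures
    shorter than 8 nt have no defined seed and are skipped with a warning.
    The same name with two different sequences is an input-integrity error.
    """
    handle = open_text(source)
    seen: dict[str, str] = {}
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(handle, "fasta"):
        name = rec.id
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) < 8:
            log.warning("skipping %s: mature length %d < 8, seed undefined", name, len(seq))
            continue
        if name in seen:
            if seen[name] != seq:
                raise ValueError(f"miRNA {name!r} appears twice with different sequences")
            continue
        seen[name] = seq
        out.append((name, seq))
    return out


def extract_seed(mature_seq: str) -> str:
    """Seed = characters at mature positions 2–8 (1-based, from the 5′ end)."""
    if len(mature_seq) < 8:
        raise ValueError(f"mature sequence of length {len(mature_seq)} < 8: seed undefined")
    return mature_seq[SEED_START:SEED_END]


def seed_to_target_motif(seed: str) -> str:
    """DNA target motif: the reverse complement of the RNA seed (U→T).

    This is the 7-mer a target 3′UTR must contain, read 5′→3′.
    """
    try:
        return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(seed))
    except KeyError as exc:
        raise ValueError(f"seed contains non-RNA character {exc.args[0]!r}") from None


def dedupe_motifs(mirna_motifs: Iterable[MirnaMotif]) -> dict[str, list[str]]:
    """Map each unique target motif to the miRNA names sharing it.

    Downstream enrichment is computed once per motif and scores broadcast to
    all member miRNAs, which is identical to computing per miRNA.
    """
    mapping: dict[str, list[str]] = {}
    for m in mirna_motifs:
        mapping.setdefault(m.target_motif, []).append(m.mirna_name)
    return mapping


def motifs_from_fasta(source: Union[PathLike, IO[str]]) -> list[MirnaMotif]:
    """Convenience: parse a mature FASTA straight into MirnaMotif records."""
    return [MirnaMotif.from_mature(name, seq) for name, seq in parse_mirna_fasta(source)]


def write_motif_table(mapping: dict[str, list[str]], path: PathLike) -> None:
    """Write motif → comma-joined miRNA names as two-column TSV."""
    with open_text(path, "wt") as fh:
        fh.write("target_motif\tmirna_names\n")
        for motif in sorted(mapping):
            fh.write(f"{motif}\t{','.join(mapping[motif])}\n")
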