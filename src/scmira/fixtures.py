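"""Synthetic data with planted, known miRNA activity.

The generator emulates the signal the activity method detects: a set of
target genes whose 3′UTRs carry a planted miRNA's target motif and whose
expression is shifted down (by δ log2 units) in the cells where the miRNA is
active.  Counts are negative-binomial (gamma–Poisson) to match scRNA-seq
overdispersion, then multinomially scaled to a fixed library size.  Every
parameter and random choice is recorded in a ``SyntheticTruth`` so a dataset
is fully reproducible from (seed, parameters).

Defaults correspond to the reference study conditions used throughout the
test-bed: 2000 genes, 200 cells (100 active), 200 targets, δ = 1.0 log2
units, 100k library, dispersion 0.3, 50 miRNAs including the planted 5p
mature and its opposite-strand 3p decoy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import PathLike
from .mirna_seeds import MirnaMotif
from .utr_sequences import BASES, UtrRecord, base_composition, write_utr_fasta

log = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset; fully determines it with the seed."""

    planted_mirna: str
    decoy_mirna: str
    target_genes: list[str]
    active_cells: list[str]
    delta: float  # log2 down-shift of target genes in active cells
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: PathLike) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _random_sequence(rng: np.random.Generator, length: int, base_probs: np.ndarray) -> str:
    idx = rng.choice(4, size=length, p=base_probs)
    lookup = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lookup[idx].tobytes().decode()


def _gc_probs(gc_content: float) -> np.ndarray:
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])  # A, C, G, T


def generate_utrs(
    n_genes: int,
    length_range: tuple[int, int] = (100, 2000),
    gc_content: float = 0.45,
    seed: int | np.random.Generator = 0,
) -> dict[str, UtrRecord]:
    """I.i.d. random UTRs with lengths uniform in ``length_range``."""
    lo, hi = length_range
    if not (20 <= lo <= hi <= 10000):
        raise ValueError("length_range must lie within [20, 10000]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = _gc_probs(gc_content)
    width = len(str(max(n_genes - 1, 1)))
    out: dict[str, UtrRecord] = {}
    for i in range(n_genes):
        gene = f"gene{i:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, probs)
        out[gene] = UtrRecord(gene, seq, length, tuple(base_composition(seq)))
    return out


def plant_motif(
    utrs: Mapping[str, UtrRecord],
    motif: str,
    target_genes: Sequence[str],
    copies: int = 1,
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
) -> dict[str, UtrRecord]:
    """Insert ``motif`` into every target's UTR; scrub it from non-targets.

    Insertion overwrites ``len(motif)`` bases at a random position (length
    preserved); for ``copies > 1`` the insertions are non-overlapping.  Any
    non-target UTR containing the motif by chance is redrawn at its own
    length and base composition until motif-free (bounded retries), so the
    indicator contrast is exact by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_set = set(target_genes)
    missing = target_set - set(utrs)
    if missing:
        raise ValueError(f"unknown target genes: {sorted(missing)[:5]}")
    k = len(motif)
    out: dict[str, UtrRecord] = {}
    for gene, rec in utrs.items():
        if gene in target_set:
            if rec.length < copies * k:
                raise ValueError(f"{gene}: UTR too short for {copies} insertion(s)")
            positions: list[int] = []
            for _ in range(max_retries):
                pos = int(rng.integers(0, rec.length - k + 1))
                if all(abs(pos - q) >= k for q in positions):
                    positions.append(pos)
                if len(positions) == copies:
                    break
            else:
                raise RuntimeError(f"{gene}: could not place {copies} non-overlapping copies")
            seq = rec.sequence
            for pos in positions:
                seq = seq[:pos] + motif + seq[pos + k:]
        else:
            seq = rec.sequence
            probs = np.asarray(rec.base_freqs)
            for attempt in range(max_retries):
                if motif not in seq:
                    break
                seq = _random_sequence(rng, rec.length, probs)
            else:
                raise RuntimeError(f"{gene}: could not draw a motif-free sequence")
        out[gene] = UtrRecord(gene, seq, rec.length, tuple(base_composition(seq)))
    return out


def random_mature(rng: np.random.Generator, length: int = 22) -> str:
    """A uniform-random mature miRNA sequence in the RNA alphabet."""
    return _random_sequence(rng, length, np.full(4, 0.25)).replace("T", "U")


def rna_reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def simulate_counts(
    utr_genes: Sequence[str],
    n_cells: int,
    truth: SyntheticTruth,
    library_size: int = 100_000,
    dispersion: float = 0.3,
    baseline_mean: float = 1.0,
    baseline_sd: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Negative-binomial counts with planted repression, scaled to fixed depth.

    Per-gene baseline log2-means ~ Normal(baseline_mean, baseline_sd); in
    active cells the target genes' means are reduced by ``truth.delta`` log2
    units.  Counts are gamma–Poisson with ``Var = m + dispersion·m²``, then
    each cell is multinomially rescaled to exactly ``library_size`` reads.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(utr_genes)
    n_genes = len(genes)
    target_idx = np.fromiter((g in set(truth.target_genes) for g in genes), bool, n_genes)
    active = set(truth.active_cells)

    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    base_means = np.exp2(mu)
    shape = 1.0 / dispersion

    width = len(str(max(n_cells - 1, 1)))
    cells = [f"cell{i:0{width}d}" for i in range(n_cells)]
    mat = np.zeros((n_genes, n_cells), dtype=np.int64)
    for j, cell in enumerate(cells):
        means = base_means.copy()
        if cell in active:
            means[target_idx] *= 2.0 ** (-truth.delta)
        lam = rng.gamma(shape, means * dispersion)
        raw = rng.poisson(lam)
        # all-zero draws (tiny gene panels): fall back to the mean profile
        weights = raw.astype(float) if raw.sum() > 0 else means
        mat[:, j] = rng.multinomial(library_size, weights / weights.sum())
    return pd.DataFrame(mat, index=genes, columns=cells)


@dataclass
class FixtureBundle:
    """A complete synthetic dataset plus its ground truth."""

    utrs: dict[str, UtrRecord]
    mirnas: list[MirnaMotif]
    counts: pd.DataFrame  # genes × cells
    labels: pd.Series  # cell → "active" | "inactive"
    truth: SyntheticTruth


def make_fixture(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 200,
    n_active: int = 100,
    n_targets: int = 200,
    n_mirnas: int = 50,
    delta: float = 1.0,
    library_size: int = 100_000,
    dispersion: float = 0.3,
    gc_content: float = 0.45,
    length_range: tuple[int, int] = (100, 2000),
    baseline_mean: float = 1.0,
    baseline_sd: float = 1.5,
    copies: int = 1,
) -> FixtureBundle:
    """Generate UTRs, a miRNA set with one planted 5p (+3p decoy), and counts.

    The planted miRNA's target motif is inserted into ``n_targets`` UTRs and
    scrubbed from the rest; its targets are repressed by ``delta`` log2 units
    in ``n_active`` of the cells.  The decoy is the opposite-strand (reverse
    complement) mature of the planted miRNA: its seed is taken from a
    different region of the duplex, so it carries no planted signal and
    probes strand specificity.
    """
    rng = np.random.default_rng(seed)
    utrs = generate_utrs(n_genes, length_range, gc_content, rng)
    genes = list(utrs)

    planted_mature = random_mature(rng)
    planted = MirnaMotif.from_mature("syn-miR-1-5p", planted_mature)
    decoy = MirnaMotif.from_mature("syn-miR-1-3p", rna_reverse_complement(planted_mature))
    while decoy.target_motif == planted.target_motif:  # vanishingly rare
        planted_mature = random_mature(rng)
        planted = MirnaMotif.from_mature("syn-miR-1-5p", planted_mature)
        decoy = MirnaMotif.from_mature("syn-miR-1-3p", rna_reverse_complement(planted_mature))

    mirnas = [planted, decoy]
    for i in range(2, n_mirnas):
        while True:
            m = MirnaMotif.from_mature(f"syn-miR-{i}-5p", random_mature(rng))
            if m.target_motif != planted.target_motif:
                break
        mirnas.append(m)

    target_genes = sorted(rng.choice(genes, size=n_targets, replace=False).tolist())
    utrs = plant_motif(utrs, planted.target_motif, target_genes, copies=copies, seed=rng)

    width = len(str(max(n_cells - 1, 1)))
    all_cells = [f"cell{i:0{width}d}" for i in range(n_cells)]
    active_cells = sorted(rng.choice(all_cells, size=n_active, replace=False).tolist())

    truth = SyntheticTruth(
        planted_mirna=planted.mirna_name,
        decoy_mirna=decoy.mirna_name,
        target_genes=target_genes,
        active_cells=active_cells,
        delta=float(delta),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        params={
            "n_genes": n_genes, "n_cells": n_cells, "n_active": n_active,
            "n_targets": n_targets, "n_mirnas": n_mirnas,
            "library_size": library_size, "dispersion": dispersion,
            "gc_content": gc_content, "length_range": list(length_range),
            "baseline_mean": baseline_mean, "baseline_sd": baseline_sd,
            "copies": copies,
        },
    )
    counts = simulate_counts(
        genes, n_cells, truth,
        library_size=library_size, dispersion=dispersion,
        baseline_mean=baseline_mean, baseline_sd=baseline_sd, seed=rng,
    )
    labels = pd.Series(
        ["active" if c in set(active_cells) else "inactive" for c in counts.columns],
        index=counts.columns, name="cell_type",
    )
    return FixtureBundle(utrs=utrs, mirnas=mirnas, counts=counts, labels=labels, truth=truth)


def write_fixture(bundle: FixtureBundle, outdir: PathLike) -> None:
    """Emit a complete fixture directory readable by the module readers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_utr_fasta(bundle.utrs.values(), out / "utrs.fa")
    with open(out / "mirnas.fa", "w") as fh:
        for m in bundle.mirnas:
            fh.write(f">{m.mirna_name}\n{m.mature_seq}\n")
    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    bundle.labels.to_frame().to_csv(out / "labels.tsv", sep="\t", index_label="cell_id")
    bundle.truth.to_json(out / "truth.json")
    log.info("wrote fixture to %s", out)
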