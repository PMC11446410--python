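"""Deterministic synthetic fixtures for every pipeline stage.

Three generators stand in for the real-world inputs the pipeline consumes:

* multi-exon target genes, emitted simultaneously in both junction
  conventions (single entry with ``N`` separators, and one-entry-per-exon);
* decoy transcriptomes of uniform-random sequence with verbatim copies of
  target segments planted at known coordinates, giving exact ground truth
  for the off-target screen;
* paired 3-D spot fields with a planted shared fraction and per-axis
  Gaussian localization jitter, emulating two detection methods run on the
  same sample.

Every generator is a pure function of its :class:`FixtureSpec` (seed
included), so fixtures are reproduced rather than stored. Truth records are
written as JSON sidecars and are computed by interval arithmetic / the
sampling plan, independently of the code paths they later test.

Default spot-field plan (260 shared + 120 A-only / 85 B-only, 100 nm
jitter) emulates the scale of a dual-method HCR-vs-smFISH comparison:
380 vs 345 spots per sample with directional overlap near 68%/75%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sequence_io import TargetSequence

__all__ = ["FixtureSpec", "make_target", "make_transcriptome", "make_spot_fields"]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Complete description of a synthetic-fixture set (seeded)."""

    seed: int = 0
    # target architecture
    n_exons: int = 3
    exon_lengths: tuple[int, ...] = (700, 600, 700)
    gc_content: float = 0.5
    # decoy transcriptome
    n_decoys: int = 8
    decoy_lengths: tuple[int, ...] = (1200,) * 8
    plants: tuple[tuple[int, int, int], ...] = ()  # (decoy_idx, target_start, length)
    # spot fields
    n_shared: int = 260
    n_a_only: int = 120
    n_b_only: int = 85
    jitter_sd_nm: float = 100.0
    # sparse field: ~1% of the box volume lies within 750 nm of a spot, so
    # chance colocalization stays negligible next to the planted overlap
    box_nm: tuple[float, float, float] = (60000.0, 60000.0, 12000.0)

    def __post_init__(self):
        if len(self.exon_lengths) != self.n_exons:
            raise ValueError("exon_lengths must have n_exons entries")
        if len(self.decoy_lengths) != self.n_decoys:
            raise ValueError("decoy_lengths must have n_decoys entries")
        if any(l <= 0 for l in self.exon_lengths + self.decoy_lengths):
            raise ValueError("all lengths must be positive")
        if self.jitter_sd_nm < 0:
            raise ValueError("jitter_sd_nm must be >= 0")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _target_from_exons(exons: list[str], gene_id: str, mode: str) -> TargetSequence:
    seq = "N".join(exons)
    bounds, pos = [], 0
    for ex in exons:
        bounds.append((pos, pos + len(ex)))
        pos += len(ex) + 1
    return TargetSequence(gene_id=gene_id, sequence=seq,
                          exon_bounds=tuple(bounds), source_mode=mode)


def make_target(spec: FixtureSpec, outdir, gene_id: str = "synthgene"):
    """Emit the same random gene in both junction conventions + truth JSON.

    Returns (single_entry_path, multi_entry_path, TargetSequence).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    exons = [_random_seq(rng, L, spec.gc_content) for L in spec.exon_lengths]
    target = _target_from_exons(exons, gene_id, "single_entry_N")

    single = outdir / f"{gene_id}_single.fa"
    single.write_text(f">{gene_id}\n{target.sequence}\n")
    multi = outdir / f"{gene_id}_exons.fa"
    with open(multi, "w") as fh:
        for i, ex in enumerate(exons, start=1):
            fh.write(f">{gene_id}_exon{i}\n{ex}\n")
    truth = {
        "gene_id": gene_id,
        "length": len(target.sequence),
        "exon_bounds": list(target.exon_bounds),
        "junction_positions": list(target.junction_positions),
    }
    (outdir / f"{gene_id}_truth.json").write_text(json.dumps(truth, indent=2))
    return single, multi, target


def make_transcriptome(
    spec: FixtureSpec,
    target: TargetSequence,
    outdir,
    window_len: int = 52,
    max_contig_match: int = 16,
):
    """Decoy transcriptome FASTA with planted verbatim target copies.

    Each plant (decoy_index, target_start, length) copies that target
    segment into the decoy at a deterministic position; the decoy bases
    immediately flanking the plant are forced to mismatch the corresponding
    target bases, so the maximal exact match equals the planted overlap
    exactly. The truth JSON lists, per plant, every candidate window start
    whose overlap with the plant exceeds ``max_contig_match`` nt (the
    windows the screen must fail), computed by interval arithmetic only.

    Returns (fasta_path, truth_path, truth_dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    decoys = [_random_seq(rng, L, spec.gc_content) for L in spec.decoy_lengths]

    tseq = target.sequence
    truth_plants = []
    for decoy_idx, t_start, length in spec.plants:
        segment = tseq[t_start : t_start + length]
        if len(segment) < length or "N" in segment:
            raise ValueError(
                f"plant ({decoy_idx},{t_start},{length}) outside target "
                "bounds or overlapping a junction"
            )
        decoy = decoys[decoy_idx]
        if length + 2 > len(decoy):
            raise ValueError(f"plant of length {length} longer than decoy {decoy_idx}")
        # deterministic placement away from the decoy ends
        d_start = 1 + int(rng.integers(0, len(decoy) - length - 1))
        new = list(decoy)
        new[d_start : d_start + length] = segment
        # force mismatching flanks so the exact match cannot extend by chance
        if d_start > 0 and t_start > 0:
            new[d_start - 1] = _mismatch_base(tseq[t_start - 1], rng)
        t_after = t_start + length
        if d_start + length < len(new) and t_after < len(tseq):
            new[d_start + length] = _mismatch_base(tseq[t_after], rng)
        decoys[decoy_idx] = "".join(new)

        # windows [s, s+w) overlapping [t_start, t_start+length) by > threshold
        failing = [
            s
            for s in range(len(tseq) - window_len + 1)
            if min(s + window_len, t_start + length) - max(s, t_start)
            > max_contig_match
            and "N" not in tseq[s : s + window_len]
        ]
        truth_plants.append(
            {
                "decoy_id": f"decoy{decoy_idx}",
                "decoy_start": d_start,
                "target_start": t_start,
                "length": length,
                "failing_window_starts": failing,
            }
        )

    fasta = outdir / "transcriptome.fa"
    with open(fasta, "w") as fh:
        for i, seq in enumerate(decoys):
            fh.write(f">decoy{i}\n{seq}\n")
    truth = {
        "window_len": window_len,
        "max_contig_match": max_contig_match,
        "plants": truth_plants,
    }
    truth_path = outdir / "transcriptome_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return fasta, truth_path, truth


def _mismatch_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, len(choices)))]


def make_spot_fields(spec: FixtureSpec, outdir, label_a: str = "hcr",
                     label_b: str = "smfish"):
    """Paired spot CSVs with a planted shared fraction + truth JSON.

    ``n_shared`` true positions are sampled uniformly in ``box_nm`` and
    duplicated into both sets with independent per-axis Gaussian jitter of
    sd ``jitter_sd_nm``; each set additionally receives its exclusive
    spots. Truth records the planned counts and the expected directional
    fractions n_shared/n_a and n_shared/n_b (exact when jitter is far below
    the matching radius and exclusive spots land away from shared ones).

    Returns (csv_a, csv_b, truth_dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)
    box = np.asarray(spec.box_nm, float)

    shared = rng.uniform(0, 1, size=(spec.n_shared, 3)) * box
    a = shared + rng.normal(0, spec.jitter_sd_nm, size=shared.shape)
    b = shared + rng.normal(0, spec.jitter_sd_nm, size=shared.shape)
    a_only = rng.uniform(0, 1, size=(spec.n_a_only, 3)) * box
    b_only = rng.uniform(0, 1, size=(spec.n_b_only, 3)) * box
    coords_a = np.vstack([a, a_only]) if spec.n_a_only else a
    coords_b = np.vstack([b, b_only]) if spec.n_b_only else b

    paths = []
    for label, coords in ((label_a, coords_a), (label_b, coords_b)):
        p = outdir / f"spots_{label}.csv"
        with open(p, "w") as fh:
            fh.write("sample_id,x,y,z\n")
            for x, y, z in coords:
                fh.write(f"s1,{x:.3f},{y:.3f},{z:.3f}\n")
        paths.append(p)

    n_a = spec.n_shared + spec.n_a_only
    n_b = spec.n_shared + spec.n_b_only
    truth = {
        "n_shared": spec.n_shared,
        "n_a": n_a,
        "n_b": n_b,
        "jitter_sd_nm": spec.jitter_sd_nm,
        "expected_frac_a_near_b": spec.n_shared / n_a if n_a else None,
        "expected_frac_b_near_a": spec.n_shared / n_b if n_b else None,
    }
    (outdir / "spots_truth.json").write_text(json.dumps(truth, indent=2))
    return paths[0], paths[1], truth
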