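"""Candidate tiling, thermodynamic filtering and non-overlapping selection.

The design pipeline mirrors how split-initiator probe sets are built in
practice: every possible window of ``2*arm_len + gap_len`` nt along the
target is enumerated (one per start position, so the tiling covers the whole
mRNA), each window's two binding arms are annotated and tested independently
against the thermodynamic windows, windows touching a masked junction ``N``
are rejected outright, the off-target screen removes cross-hybridizing
windows, and a final non-overlapping set is selected along the target.

Selection offers two modes. ``max_count`` maximizes the number of probes via
the greedy earliest-end scan, which is provably optimal for unweighted
non-overlapping interval selection. ``even_spread`` returns a requested
number of probes maximizing the minimum inter-probe spacing (binary search
on spacing with a greedy feasibility check) — a reading of "distributed
along the target" that favors coverage over count. Fewer than five final
pairs triggers the FEWER_THAN_MIN_PAIRS warning, reflecting the recommended
minimum for sufficient fluorescent signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Optional

from .thermo import (
    ThermoConfig,
    gc_fraction,
    max_homopolymer_run,
    melting_temperature,
)
from .sequence_io import TargetSequence, TranscriptomeIndex

if TYPE_CHECKING:  # pragma: no cover
    from .offtarget import OfftargetConfig, OfftargetHit
    from .assembly import InitiatorSpec, ProbePair

__all__ = [
    "DesignConfig",
    "CandidateProbe",
    "DesignResult",
    "enumerate_candidates",
    "apply_thermo_filter",
    "select_nonoverlapping",
    "design",
]

# filter reason codes
CONTAINS_N = "CONTAINS_N"
GC_RANGE = "GC_RANGE"
TM_RANGE = "TM_RANGE"
HOMOPOLYMER = "HOMOPOLYMER"
OFFTARGET = "OFFTARGET"

# warning codes
NO_CANDIDATES = "NO_CANDIDATES"
FEWER_THAN_MIN_PAIRS = "FEWER_THAN_MIN_PAIRS"


@dataclass
class DesignConfig:
    """Geometry and policy for a probe design run.

    ``arm_len`` (default 25) and ``gap_len`` (default 2) give the canonical
    25 + 2 + 25 = 52 nt split-probe window: two binding arms separated by a
    2-nt unbound target gap. ``min_inter_probe_gap`` nt are kept between
    consecutive selected windows. ``target_pairs`` = 0 means "as many as
    fit"; ``min_pairs_warn`` (default 5) is the sufficiency threshold below
    which a warning is raised.
    """

    arm_len: int = 25
    gap_len: int = 2
    min_inter_probe_gap: int = 2
    target_pairs: int = 0
    min_pairs_warn: int = 5
    selection_mode: str = "max_count"  # or "even_spread"
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    offtarget: "Optional[OfftargetConfig]" = None

    def __post_init__(self):
        if self.arm_len < 10:
            raise ValueError("arm_len must be >= 10")
        if self.gap_len < 0 or self.min_inter_probe_gap < 0:
            raise ValueError("gap lengths must be >= 0")
        if self.min_pairs_warn < 1:
            raise ValueError("min_pairs_warn must be >= 1")
        if self.selection_mode not in ("max_count", "even_spread"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.offtarget is None:
            from .offtarget import OfftargetConfig

            self.offtarget = OfftargetConfig()

    @property
    def window_len(self) -> int:
        return 2 * self.arm_len + self.gap_len


@dataclass
class CandidateProbe:
    """One tiled window with per-arm annotations and filter verdicts."""

    start: int
    end: int
    arm1_seq: str = ""
    arm2_seq: str = ""
    tm_arm1_c: Optional[float] = None
    tm_arm2_c: Optional[float] = None
    gc_arm1: Optional[float] = None
    gc_arm2: Optional[float] = None
    fail_reasons: list[str] = field(default_factory=list)
    offtarget_hits: list = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "pass" if not self.fail_reasons else "fail"

    def add_reason(self, reason: str) -> None:
        if reason not in self.fail_reasons:
            self.fail_reasons.append(reason)


@dataclass
class DesignResult:
    """Full pipeline output: candidates, selection, pairs, warnings."""

    target: TargetSequence
    candidates: list[CandidateProbe]
    selected: list[CandidateProbe]
    pairs: "list[ProbePair]"
    warnings: list[str]

    def to_json(self, indent: int = 2) -> str:
        """Deterministic JSON serialization of the full result."""
        payload = {
            "gene_id": self.target.gene_id,
            "target_length": len(self.target.sequence),
            "exon_bounds": list(self.target.exon_bounds),
            "n_candidates": len(self.candidates),
            "n_passing": sum(1 for c in self.candidates if c.verdict == "pass"),
            "warnings": self.warnings,
            "candidates": [
                {
                    "start": c.start,
                    "end": c.end,
                    "verdict": c.verdict,
                    "fail_reasons": c.fail_reasons,
                    "tm_arm1_c": c.tm_arm1_c,
                    "tm_arm2_c": c.tm_arm2_c,
                    "gc_arm1": c.gc_arm1,
                    "gc_arm2": c.gc_arm2,
                }
                for c in self.candidates
            ],
            "selected_starts": [c.start for c in self.selected],
            "pairs": [asdict(p) for p in self.pairs],
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def enumerate_candidates(
    target: TargetSequence, cfg: DesignConfig
) -> list[CandidateProbe]:
    """All windows of ``cfg.window_len`` along the target, in start order.

    Windows containing any ``N`` (i.e. spanning an exon junction) are
    emitted with verdict fail and reason CONTAINS_N and carry no arm
    annotations; all others carry arm sequences, GC and Tm.
    """
    seq = target.sequence
    w = cfg.window_len
    if len(seq) < w:
        raise ValueError(
            f"target length {len(seq)} is shorter than the probe window; "
            f"need at least {w} nt"
        )
    out: list[CandidateProbe] = []
    for start in range(len(seq) - w + 1):
        end = start + w
        window = seq[start:end]
        cand = CandidateProbe(start=start, end=end)
        if "N" in window:
            cand.add_reason(CONTAINS_N)
        else:
            cand.arm1_seq = window[: cfg.arm_len]
            cand.arm2_seq = window[cfg.arm_len + cfg.gap_len :]
            cand.gc_arm1 = gc_fraction(cand.arm1_seq)
            cand.gc_arm2 = gc_fraction(cand.arm2_seq)
            cand.tm_arm1_c = melting_temperature(cand.arm1_seq, cfg.thermo)
            cand.tm_arm2_c = melting_temperature(cand.arm2_seq, cfg.thermo)
        out.append(cand)
    return out


def apply_thermo_filter(
    cands: list[CandidateProbe], cfg: DesignConfig
) -> list[CandidateProbe]:
    """Test each arm independently against GC/Tm windows and max_run.

    Pure annotation: reasons are appended (no duplicates, so re-application
    is idempotent); candidates already failed for CONTAINS_N are skipped.
    """
    t = cfg.thermo
    for cand in cands:
        if CONTAINS_N in cand.fail_reasons:
            continue
        for gc in (cand.gc_arm1, cand.gc_arm2):
            if not (t.gc_min <= gc <= t.gc_max):
                cand.add_reason(GC_RANGE)
        for tm in (cand.tm_arm1_c, cand.tm_arm2_c):
            if not (t.tm_min_c <= tm <= t.tm_max_c):
                cand.add_reason(TM_RANGE)
        for arm in (cand.arm1_seq, cand.arm2_seq):
            if max_homopolymer_run(arm) > t.max_run:
                cand.add_reason(HOMOPOLYMER)
    return cands


def _greedy_earliest_end(
    passing: list[CandidateProbe], spacing: int
) -> list[CandidateProbe]:
    """Greedy scan over candidates sorted by (end, start)."""
    chosen: list[CandidateProbe] = []
    last_end = None
    for cand in sorted(passing, key=lambda c: (c.end, c.start)):
        if last_end is None or cand.start >= last_end + spacing:
            chosen.append(cand)
            last_end = cand.end
    return chosen


def select_nonoverlapping(
    cands: list[CandidateProbe], cfg: DesignConfig
) -> tuple[list[CandidateProbe], list[str]]:
    """Select a final non-overlapping window set from passing candidates.

    Returns ``(selected, warnings)``. In ``max_count`` mode the greedy
    earliest-end scan yields a maximum-cardinality set with
    ``min_inter_probe_gap`` nt between consecutive windows. In
    ``even_spread`` mode (requires ``target_pairs > 0``) a binary search on
    spacing with greedy feasibility finds min(target_pairs, achievable)
    windows maximizing the minimum spacing. Ties always break toward the
    smaller start coordinate, so selection is deterministic.
    """
    passing = [c for c in cands if c.verdict == "pass"]
    if not passing:
        return [], [NO_CANDIDATES]

    if cfg.selection_mode == "max_count":
        return _greedy_earliest_end(passing, cfg.min_inter_probe_gap), []

    if cfg.target_pairs <= 0:
        raise ValueError("even_spread selection requires target_pairs > 0")
    achievable = len(_greedy_earliest_end(passing, cfg.min_inter_probe_gap))
    m = min(cfg.target_pairs, achievable)
    # binary search the largest spacing for which m windows fit
    lo = cfg.min_inter_probe_gap
    hi = max(c.end for c in passing) - min(c.start for c in passing)
    best = _greedy_earliest_end(passing, cfg.min_inter_probe_gap)[:m]
    while lo <= hi:
        mid = (lo + hi) // 2
        sel = _greedy_earliest_end(passing, mid)
        if len(sel) >= m:
            best = sel[:m]
            lo = mid + 1
        else:
            hi = mid - 1
    return best, []


def design(
    target: TargetSequence,
    transcriptome: Optional[TranscriptomeIndex] = None,
    cfg: Optional[DesignConfig] = None,
    initiator: "Optional[InitiatorSpec]" = None,
) -> DesignResult:
    """Run the full pipeline: tile, filter, screen, select, assemble.

    ``transcriptome`` may be None to skip the off-target screen (e.g. when
    the external BLAST backend was used separately). ``initiator`` may be
    None to skip pair assembly (selection only).
    """
    from .offtarget import apply_offtarget_filter
    from .assembly import split_and_assemble

    cfg = cfg or DesignConfig()
    warnings: list[str] = []
    cands = enumerate_candidates(target, cfg)
    apply_thermo_filter(cands, cfg)
    if transcriptome is not None:
        apply_offtarget_filter(cands, transcriptome, cfg.offtarget, target.sequence)
    selected, sel_warnings = select_nonoverlapping(cands, cfg)
    warnings.extend(sel_warnings)

    pairs = []
    if initiator is not None and selected:
        pairs = split_and_assemble(selected, initiator, cfg, gene_id=target.gene_id)
    n_final = len(pairs) if initiator is not None else len(selected)
    if n_final < cfg.min_pairs_warn:
        warnings.append(FEWER_THAN_MIN_PAIRS)
    return DesignResult(
        target=target,
        candidates=cands,
        selected=selected,
        pairs=pairs,
        warnings=warnings,
    )
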