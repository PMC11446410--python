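"""Off-target screening of candidate windows against a transcriptome.

A probe that shares a long contiguous stretch with another transcript can
hybridize there and produce false signal. The screen therefore rejects any
candidate whose 52-nt target window shares a contiguous exact match longer
than ``max_contig_match`` nt (default 16; a 17-nt match fails) with any
transcript other than the target's own isoforms. Only the sense strand is
compared: probes are antisense to the target mRNA, so a probe can only bind
another transcript where that transcript is sense-identical to the target
window.

Two backends exist. The default internal backend is a deterministic k-mer
seed-and-extend over a :class:`~hcrkit.sequence_io.TranscriptomeIndex` —
every maximal exact match of length >= ``seed_k`` is found, because any such
match must contain at least one aligned seed k-mer. The optional ``blastn``
backend shells out to NCBI BLAST+ (task ``blastn-short``) against a
pre-built nucleotide database and maps the longest contiguous identity
stretch of each plus-strand alignment (parsed from the BTOP string) onto the
same hit type. Contiguous-match length is a deterministic proxy for
cross-hybridization, not a thermodynamic model.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .design import CandidateProbe, OFFTARGET
from .sequence_io import TranscriptomeIndex

__all__ = [
    "OfftargetConfig",
    "OfftargetHit",
    "BlastNotFoundError",
    "find_offtargets",
    "apply_offtarget_filter",
    "blastn_screen",
]


class BlastNotFoundError(RuntimeError):
    """blastn executable not on PATH; use backend='internal' instead."""


@dataclass
class OfftargetConfig:
    """Screen parameters.

    ``seed_k``: internal-backend seed length (nt). ``max_contig_match``:
    longest tolerated contiguous exact match to a non-target transcript; a
    match of ``max_contig_match + 1`` or more fails the candidate.
    ``exclude_ids``: transcript ids exempt from screening (the target gene's
    own isoforms). ``screen_failed``: also screen candidates that already
    failed the thermo filter (off by default, for speed).
    """

    seed_k: int = 15
    max_contig_match: int = 16
    exclude_ids: tuple[str, ...] = ()
    backend: str = "internal"  # or "blastn"
    blast_evalue: float = 1.0
    screen_failed: bool = False

    def __post_init__(self):
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.seed_k > self.max_contig_match + 1:
            raise ValueError(
                "seed_k must be <= max_contig_match + 1, otherwise a "
                "disqualifying match could be missed"
            )
        if self.backend not in ("internal", "blastn"):
            raise ValueError(f"unknown backend {self.backend!r}")
        self.exclude_ids = tuple(self.exclude_ids)


@dataclass(frozen=True)
class OfftargetHit:
    """One maximal contiguous exact match between a window and a subject."""

    candidate_start: int
    subject_id: str
    subject_pos: int
    match_len: int
    query_offset: int  # match start within the window
    arm: str  # "arm1", "arm2", "both", or "gap"


def _arm_overlap(q_start: int, q_end: int, arm_len: int, gap_len: int) -> str:
    in1 = q_start < arm_len
    in2 = q_end > arm_len + gap_len
    if in1 and in2:
        return "both"
    if in1:
        return "arm1"
    if in2:
        return "arm2"
    return "gap"


def find_offtargets(
    cand: CandidateProbe,
    index: TranscriptomeIndex,
    cfg: OfftargetConfig,
    window: str | None = None,
) -> list[OfftargetHit]:
    """All maximal exact matches >= seed_k between a window and non-excluded
    transcripts, each reported exactly once with its maximal extension.

    ``window`` defaults to ``arm1 + gap + arm2`` reconstructed from the
    candidate; pass it explicitly when the gap bases matter (it is read from
    the candidate's annotations otherwise).
    """
    if index.k != cfg.seed_k:
        raise ValueError(
            f"index built with k={index.k} but cfg.seed_k={cfg.seed_k}"
        )
    if window is None:
        raise ValueError(
            "find_offtargets requires the window sequence (the candidate "
            "does not store the gap bases)"
        )
    k = cfg.seed_k
    arm_len = len(cand.arm1_seq)
    gap_len = (cand.end - cand.start) - 2 * arm_len
    excluded = set(cfg.exclude_ids)
    seen: set[tuple[str, int, int, int]] = set()
    hits: list[OfftargetHit] = []
    for qo in range(len(window) - k + 1):
        seed = window[qo : qo + k]
        if "N" in seed:
            continue
        for tid, tpos in index.lookup(seed):
            if tid in excluded:
                continue
            subject = index.records[tid]
            # extend left
            qs, ss = qo, tpos
            while qs > 0 and ss > 0 and window[qs - 1] == subject[ss - 1] \
                    and subject[ss - 1] != "N":
                qs -= 1
                ss -= 1
            # extend right
            qe, se = qo + k, tpos + k
            while (
                qe < len(window)
                and se < len(subject)
                and window[qe] == subject[se]
                and subject[se] != "N"
            ):
                qe += 1
                se += 1
            key = (tid, qs, ss, qe - qs)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                OfftargetHit(
                    candidate_start=cand.start,
                    subject_id=tid,
                    subject_pos=ss,
                    match_len=qe - qs,
                    query_offset=qs,
                    arm=_arm_overlap(qs, qe, arm_len, gap_len),
                )
            )
    hits.sort(key=lambda h: (h.subject_id, h.subject_pos, -h.match_len))
    return hits


def apply_offtarget_filter(
    cands: list[CandidateProbe],
    index: TranscriptomeIndex,
    cfg: OfftargetConfig,
    target_sequence: str,
) -> list[CandidateProbe]:
    """Append OFFTARGET to candidates with a match > max_contig_match.

    Hits are retained on each candidate record for reporting. By default
    only candidates still passing are screened; set ``cfg.screen_failed``
    to screen everything.
    """
    for cand in cands:
        if cand.fail_reasons and not cfg.screen_failed:
            continue
        if not cand.arm1_seq:  # CONTAINS_N window, nothing to screen
            continue
        window = target_sequence[cand.start : cand.end]
        hits = find_offtargets(cand, index, cfg, window=window)
        cand.offtarget_hits = hits
        if any(h.match_len > cfg.max_contig_match for h in hits):
            cand.add_reason(OFFTARGET)
    return cands


def _max_identity_run(btop: str) -> int:
    """Longest contiguous identity stretch encoded in a BLAST BTOP string."""
    best = 0
    num = ""
    for ch in btop:
        if ch.isdigit():
            num += ch
        else:
            if num:
                best = max(best, int(num))
                num = ""
    if num:
        best = max(best, int(num))
    return best


def blastn_screen(
    cands: list[CandidateProbe],
    db_path,
    cfg: OfftargetConfig,
    target_sequence: str,
) -> list[OfftargetHit]:
    """Screen candidate windows with external ``blastn -task blastn-short``.

    Plus-strand alignments only (sense-strand criterion); each alignment is
    reduced to its longest contiguous identity run (from BTOP) and reported
    as an :class:`OfftargetHit` when that run reaches ``seed_k``. Subject
    ids in ``exclude_ids`` are dropped.
    """
    if shutil.which("blastn") is None:
        raise BlastNotFoundError(
            "blastn executable not found on PATH; install NCBI BLAST+ or run "
            "the screen with backend='internal'"
        )
    excluded = set(cfg.exclude_ids)
    screenable = [c for c in cands if c.arm1_seq]
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "windows.fa"
        with open(qpath, "w") as fh:
            for c in screenable:
                fh.write(f">cand_{c.start}\n{target_sequence[c.start:c.end]}\n")
        cmd = [
            "blastn",
            "-task",
            "blastn-short",
            "-query",
            str(qpath),
            "-db",
            str(db_path),
            "-evalue",
            str(cfg.blast_evalue),
            "-strand",
            "plus",
            "-dust",
            "no",
            "-outfmt",
            "6 qseqid sseqid qstart qend sstart send length mismatch gapopen btop",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"blastn failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        hits: list[OfftargetHit] = []
        for line in proc.stdout.splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise RuntimeError(f"unparseable blastn output line: {line!r}")
            qseqid, sseqid, qstart, qend, sstart, send = parts[:6]
            btop = parts[9]
            if sseqid in excluded:
                continue
            run = _max_identity_run(btop)
            if run < cfg.seed_k:
                continue
            cand_start = int(qseqid.split("_")[1])
            hits.append(
                OfftargetHit(
                    candidate_start=cand_start,
                    subject_id=sseqid,
                    subject_pos=int(sstart) - 1,
                    match_len=run,
                    query_offset=int(qstart) - 1,
                    arm="",
                )
            )
    hits.sort(key=lambda h: (h.candidate_start, h.subject_id, h.subject_pos))
    return hits
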