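"""Split-probe assembly, hybridization validation, order sheets, probe map.

Each selected 52-nt window is split into a probe pair. Each oligo has three
sections: a 25-nt binding arm (reverse complement of its target arm), a
short flexible connector, and one 18-nt half of a 36-nt HCR initiator. Only
when both probes bind their adjacent target sites is the full initiator
presented, which is what triggers hairpin amplification — a single
non-specifically bound probe carries only half and stays dark.

Oligo layout convention (arm1 = 5'-proximal target arm, arm2 = 3'-proximal):

    oligo_P1 = half_up + conn_up + revcomp(arm2)
    oligo_P2 = revcomp(arm1) + conn_dn + half_dn

The layout is deliberately swappable: :func:`validate_pair`, which simulates
antiparallel hybridization onto the target window and reads the initiator
halves off the bound complex, is the source of truth. Any layout whose
read-off reconstitutes the full initiator passes; vendor-issued layouts can
be substituted by editing the registry file and the assembly convention
without touching the validator.

B1-B5 initiator sequences ship in an editable TSV registry
(``data/initiators.tsv``, published HCR v3 amplifier definitions); users
with vendor-issued sequences substitute their own file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .design import CandidateProbe, DesignConfig, DesignResult
from .thermo import reverse_complement
from .sequence_io import TargetSequence

__all__ = [
    "InitiatorSpec",
    "ProbePair",
    "HybridizationCheck",
    "load_initiators",
    "default_initiators",
    "split_and_assemble",
    "validate_pair",
    "write_order_sheet",
    "probe_map_report",
]

_ACGT = set("ACGT")

POOLING_NOTE = (
    "Pool oligos at 100 µM stock concentration; keep aliquots at "
    "1 µM working concentration."
)


@dataclass(frozen=True)
class InitiatorSpec:
    """One B-series initiator: full 36-nt sequence, halves, connectors."""

    id: str
    full_seq: str
    half_up: str
    half_dn: str
    conn_up: str = "AA"
    conn_dn: str = "TT"

    def __post_init__(self):
        if len(self.half_up) != 18 or len(self.half_dn) != 18:
            raise ValueError(
                f"initiator {self.id}: halves must be 18 nt, got "
                f"{len(self.half_up)}/{len(self.half_dn)}"
            )
        if self.half_up + self.half_dn != self.full_seq:
            raise ValueError(
                f"initiator {self.id}: halves do not concatenate to full_seq"
            )
        for name in ("full_seq", "half_up", "half_dn", "conn_up", "conn_dn"):
            val = getattr(self, name)
            if set(val) - _ACGT:
                raise ValueError(
                    f"initiator {self.id}: {name} contains non-ACGT characters"
                )


@dataclass
class ProbePair:
    """Two final oligos covering one target window."""

    pair_index: int
    window_start: int
    window_end: int
    oligo_P1: str
    oligo_P2: str
    initiator_id: str
    tm_arm1_c: float
    tm_arm2_c: float


@dataclass
class HybridizationCheck:
    """Outcome of simulating the pair bound to its target window."""

    pair: ProbePair
    target_window: str
    reconstructed_initiator: str
    ok: bool


def load_initiators(path=None) -> dict[str, InitiatorSpec]:
    """Load an initiator registry TSV (id, full_seq, half_up, half_dn,
    conn_up, conn_dn). Defaults to the packaged B1-B5 file. Raises on
    malformed rows or invariant violations, naming the offending record.
    """
    if path is None:
        path = resources.files("hcrkit.data").joinpath("initiators.tsv")
    registry: dict[str, InitiatorSpec] = {}
    with open(path) as fh:
        rows = [
            line.rstrip("\n").split("\t")
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    if not rows or rows[0][:2] != ["id", "full_seq"]:
        raise ValueError(f"{path}: missing header 'id\\tfull_seq\\t...'")
    header = rows[0]
    for row in rows[1:]:
        rec = dict(zip(header, row))
        try:
            spec = InitiatorSpec(
                id=rec["id"],
                full_seq=rec["full_seq"],
                half_up=rec["half_up"],
                half_dn=rec["half_dn"],
                conn_up=rec.get("conn_up", "AA"),
                conn_dn=rec.get("conn_dn", "TT"),
            )
        except KeyError as exc:
            raise ValueError(f"{path}: row {row!r} missing column {exc}") from exc
        if spec.id in registry:
            raise ValueError(f"{path}: duplicate initiator id {spec.id!r}")
        registry[spec.id] = spec
    return registry


def default_initiators() -> dict[str, InitiatorSpec]:
    return load_initiators()


def split_and_assemble(
    selected: list[CandidateProbe],
    spec: InitiatorSpec,
    cfg: DesignConfig,
    gene_id: str = "",
) -> list[ProbePair]:
    """One ProbePair per selected window, pair_index ascending with start."""
    pairs = []
    for idx, cand in enumerate(sorted(selected, key=lambda c: c.start), start=1):
        pairs.append(
            ProbePair(
                pair_index=idx,
                window_start=cand.start,
                window_end=cand.end,
                oligo_P1=spec.half_up + spec.conn_up + reverse_complement(cand.arm2_seq),
                oligo_P2=reverse_complement(cand.arm1_seq) + spec.conn_dn + spec.half_dn,
                initiator_id=spec.id,
                tm_arm1_c=cand.tm_arm1_c,
                tm_arm2_c=cand.tm_arm2_c,
            )
        )
    return pairs


def validate_pair(
    pair: ProbePair, target: TargetSequence, spec: InitiatorSpec
) -> HybridizationCheck:
    """Simulate antiparallel hybridization and read off the initiator.

    Arm lengths are inferred from the oligos themselves (oligo = 18-nt half
    + connector + arm), so any geometry assembled by this package — or a
    hand-built pair — is checked against the same contract: both arms must
    bind their target sub-windows with zero mismatches, and the two unbound
    initiator halves, read 5'->3' in the order they present on the bound
    complex, must reconstitute ``spec.full_seq`` exactly.
    """
    if not (0 <= pair.window_start < pair.window_end <= len(target.sequence)):
        raise ValueError(
            f"window ({pair.window_start},{pair.window_end}) outside target "
            f"of length {len(target.sequence)}"
        )
    window = target.sequence[pair.window_start : pair.window_end]
    arm2_len = len(pair.oligo_P1) - 18 - len(spec.conn_up)
    arm1_len = len(pair.oligo_P2) - 18 - len(spec.conn_dn)
    ok = arm1_len > 0 and arm2_len > 0 and len(window) >= arm1_len + arm2_len
    arm1 = window[:arm1_len] if ok else ""
    arm2 = window[len(window) - arm2_len :] if ok else ""

    # P1 binds arm2 via its 3'-terminal binding section; P2 binds arm1 via
    # its 5'-terminal binding section. Mismatch-free binding required.
    if ok:
        ok = pair.oligo_P1[-arm2_len:] == reverse_complement(arm2)
    if ok:
        ok = pair.oligo_P2[:arm1_len] == reverse_complement(arm1)

    # Unbound overhangs, connectors stripped: P1 presents its 5' overhang
    # (upstream half first, read 5'->3'), P2 its 3' overhang (downstream
    # half). Presentation order on the complex: up-half then down-half.
    read_up = pair.oligo_P1[: len(pair.oligo_P1) - arm2_len - len(spec.conn_up)]
    read_dn = pair.oligo_P2[arm1_len + len(spec.conn_dn) :]
    reconstructed = read_up + read_dn
    ok = ok and reconstructed == spec.full_seq
    return HybridizationCheck(
        pair=pair, target_window=window, reconstructed_initiator=reconstructed, ok=ok
    )


def _well_name(i: int) -> str:
    """Row-major 96-well position for 0-based index i: A1..A12, B1.."""
    return f"{chr(ord('A') + i // 12)}{i % 12 + 1}"


def _sheet_rows(pairs: list[ProbePair], gene_id: str) -> list[dict]:
    rows = []
    i = 0
    for p in pairs:
        for suffix, oligo in (("P1", p.oligo_P1), ("P2", p.oligo_P2)):
            rows.append(
                {
                    "Well": _well_name(i),
                    "Name": f"{gene_id}_{p.initiator_id}_{p.pair_index:02d}_{suffix}",
                    "Sequence": oligo,
                    "Scale": "25nm",
                    "Purification": "STD",
                }
            )
            i += 1
    return rows


def write_order_sheet(
    pairs: list[ProbePair], path, gene_id: str = "probe", fmt: str | None = None
) -> None:
    """Write the oligo order sheet (one row per oligo, 5'->3' sequences).

    CSV: a leading '#' comment carries the pooling note, then plain CSV —
    re-reading reproduces every sequence byte-identically. XLSX: an "oligos"
    sheet plus a 96-well "plate" layout (row-major A1, A2, ...), with the
    pooling note on both.
    """
    if not pairs:
        raise ValueError("write_order_sheet: no pairs to write")
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    rows = _sheet_rows(pairs, gene_id)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# {POOLING_NOTE}\n")
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "xlsx":
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = "oligos"
        ws.append(list(rows[0]))
        for row in rows:
            ws.append(list(row.values()))
        ws.append([])
        ws.append([POOLING_NOTE])
        plate = wb.create_sheet("plate")
        plate.append([""] + [str(c) for c in range(1, 13)])
        for r in range(8):
            plate.append([chr(ord("A") + r)] + [""] * 12)
        for i, row in enumerate(rows):
            plate.cell(row=2 + i // 12, column=2 + i % 12, value=row["Name"])
        plate.append([])
        plate.append([POOLING_NOTE])
        wb.save(path)
    else:
        raise ValueError(f"unknown order sheet format {fmt!r}")


def read_order_sheet(path) -> list[dict]:
    """Re-read a CSV order sheet written by :func:`write_order_sheet`."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines))


def probe_map_report(
    result: DesignResult, out_prefix, fig_format: str = "png"
) -> tuple[Path, Path | None]:
    """Write the probe-map text summary and (when pairs exist) the figure.

    The figure draws the target as an axis with selected windows as
    intervals annotated with per-arm Tm, junctions marked; the text summary
    lists per-pair 1-based inclusive coordinates, Tm and GC. Returns
    (summary_path, figure_path or None).
    """
    out_prefix = Path(out_prefix)
    summary_path = out_prefix.with_suffix(".txt")
    by_start = {c.start: c for c in result.selected}
    lines = [
        f"Probe map for {result.target.gene_id}",
        f"Target length: {len(result.target.sequence)} nt "
        f"({len(result.target.exon_bounds)} exon(s))",
        "Coordinates are 1-based inclusive on the junction-masked target.",
    ]
    junctions = result.target.junction_positions
    if junctions:
        lines.append(
            "Junctions (masked N) at: "
            + ", ".join(str(j + 1) for j in junctions)
        )
    if not result.pairs:
        lines.append("NO_CANDIDATES: no probe pairs were designed.")
    else:
        lines.append(
            f"{'pair':>4} {'start':>6} {'end':>6} {'Tm_arm1_C':>9} "
            f"{'Tm_arm2_C':>9} {'GC_arm1':>7} {'GC_arm2':>7}"
        )
        for p in result.pairs:
            cand = by_start[p.window_start]
            lines.append(
                f"{p.pair_index:>4} {p.window_start + 1:>6} {p.window_end:>6} "
                f"{p.tm_arm1_c:>9.2f} {p.tm_arm2_c:>9.2f} "
                f"{cand.gc_arm1:>7.2f} {cand.gc_arm2:>7.2f}"
            )
    for w in result.warnings:
        lines.append(f"WARNING: {w}")
    summary_path.write_text("\n".join(lines) + "\n")

    fig_path = None
    if result.pairs:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 2.5))
        L = len(result.target.sequence)
        ax.hlines(0, 1, L, color="0.6", lw=3)
        for j in junctions:
            ax.axvline(j + 1, color="red", lw=1, ls="--")
        for p in result.pairs:
            ax.hlines(0.15, p.window_start + 1, p.window_end, lw=6, color="tab:blue")
            ax.annotate(
                f"{(p.tm_arm1_c + p.tm_arm2_c) / 2:.1f}°C",
                ((p.window_start + p.window_end) / 2, 0.25),
                ha="center",
                fontsize=7,
            )
        ax.set_ylim(-0.2, 0.5)
        ax.set_xlim(0, L + 1)
        ax.set_yticks([])
        ax.set_xlabel(
            f"{result.target.gene_id} position (nt, 1-based); "
            "red dashes mark exon junctions"
        )
        fig.tight_layout()
        fig_path = out_prefix.with_suffix(f".{fig_format}")
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return summary_path, fig_path
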