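"""Per-arm thermodynamic annotations: melting temperature, GC, homopolymers.

Each 25-nt binding arm hybridizes as an independent DNA:DNA duplex, scored
with the unified nearest-neighbor model (SantaLucia 1998 parameter set, the
biopython ``DNA_NN3`` table) under the two-state, non-self-complementary
assumption at total strand concentration ``oligo_conc_molar`` (C_T/4 term).
Monovalent salt enters through the SantaLucia (1998) entropy correction
0.368*(N-1)*ln[Na+] at ``na_molar`` — GC-independent, hence Tm is strictly
increasing in salt for every sequence; formamide is applied last as a pure
-0.6 degC per volume-percent offset (Blake & Delcourt style linear
correction).

Defaults follow the hybridization buffer the probes are used in: 5xSSC
(0.75 M Na+), 30% formamide, 10 nM probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "ThermoConfig",
    "gc_fraction",
    "max_homopolymer_run",
    "melting_temperature",
    "reverse_complement",
]

_ACGT = set("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")

#: formamide destabilization, degC per volume percent
FORMAMIDE_SLOPE_C_PER_PCT = 0.6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ThermoConfig:
    """Hybridization conditions and per-arm acceptance windows.

    Parameters
    ----------
    na_molar : float
        Monovalent cation concentration in mol/L (default 0.75, i.e. 5xSSC).
    formamide_pct : float
        Volume percent formamide in the hybridization buffer (default 30).
    oligo_conc_molar : float
        Total probe strand concentration in mol/L (default 1e-8 = 10 nM).
    tm_min_c, tm_max_c : float
        Accepted per-arm Tm window in degC, after the formamide correction
        (default [40, 60]).
    gc_min, gc_max : float
        Accepted per-arm GC fraction window (default [0.35, 0.65]).
    max_run : int
        Longest tolerated homopolymer run in nt (default 4).
    """

    na_molar: float = 0.75
    formamide_pct: float = 30.0
    oligo_conc_molar: float = 1e-8
    tm_min_c: float = 40.0
    tm_max_c: float = 60.0
    gc_min: float = 0.35
    gc_max: float = 0.65
    max_run: int = 4

    def __post_init__(self):
        if not self.tm_min_c < self.tm_max_c:
            raise ValueError("tm_min_c must be < tm_max_c")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if self.na_molar <= 0 or self.oligo_conc_molar <= 0:
            raise ValueError("concentrations must be > 0")
        if self.formamide_pct < 0:
            raise ValueError("formamide_pct must be >= 0")


def _check_acgt(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"{op}: sequence contains non-ACGT characters {sorted(bad)}")


def gc_fraction(seq: str) -> float:
    """(G + C) / length for an N-free sequence."""
    _check_acgt(seq, "gc_fraction")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one repeated base."""
    if not seq:
        raise ValueError("max_homopolymer_run: empty sequence")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def melting_temperature(seq: str, cfg: ThermoConfig | None = None) -> float:
    """Duplex Tm in degC for a DNA oligo against its perfect complement.

    Unified nearest-neighbor dH/dS summation with initiation and terminal-AT
    terms, C_T/4 concentration term (non-self-complementary two-state model),
    SantaLucia 1998 entropic monovalent-salt correction, then the linear
    formamide offset. Deterministic; 8 <= len(seq) <= 60 and N-free required.
    """
    cfg = cfg or ThermoConfig()
    _check_acgt(seq, "melting_temperature")
    if not (8 <= len(seq) <= 60):
        raise ValueError(
            f"melting_temperature: length {len(seq)} outside supported [8, 60]"
        )
    conc_nm = cfg.oligo_conc_molar * 1e9
    # a duplex and its reverse complement are the same molecule: canonicalize
    # so Tm(s) == Tm(revcomp(s)) holds exactly, not merely to rounding
    canonical = min(seq, reverse_complement(seq))
    tm = _mt.Tm_NN(
        canonical,
        nn_table=_mt.DNA_NN3,
        # dnac1 - dnac2/2 = C_T/4: the standard non-self-complementary term
        dnac1=conc_nm / 2.0,
        dnac2=conc_nm / 2.0,
        selfcomp=False,
        Na=cfg.na_molar * 1000.0,
        K=0,
        Tris=0,
        Mg=0,
        dNTPs=0,
        saltcorr=5,
    )
    return tm - FORMAMIDE_SLOPE_C_PER_PCT * cfg.formamide_pct
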