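"""Padlock probe and detection-oligo design.

A padlock probe is a linear DNA oligo whose two terminal arms are
complementary to adjacent halves of a 40–45-nt window on the target mRNA;
when both arms hybridize, the probe ends abut at a nick (the ligation
junction) that SplintR ligase seals, licensing rolling-circle
amplification.  Arms are chosen so the combined target duplex melts near
70 °C, and the fluorophore-carrying detection oligo — a U-substituted
subsequence of the probe's gene-specific backbone region — is trimmed to
Tm ≈ 56 °C so it can be stripped enzymatically between cycles.

Melting temperatures come from unified nearest-neighbor DNA/DNA
thermodynamics (SantaLucia & Hicks 2004 ΔH/ΔS parameters) with the
entropic monovalent-salt correction ΔS += 0.368·(N−1)·ln[Na+] and the
CT/4 two-state formula for non-self-complementary duplexes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

#: Unified DNA/DNA nearest-neighbor parameters (ΔH kcal/mol, ΔS cal/mol·K).
NN_PARAMS = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INITIATION = (0.2, -5.7)
TERMINAL_AT = (2.2, 6.9)  # per A·T end
GAS_CONSTANT = 1.987  # cal/(mol·K)

#: defaults matching the assay conditions: 0.05 µM probe, 0.05 M KCl.
DEFAULT_OLIGO_CONC_M = 5e-8
DEFAULT_SALT_M = 0.05

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(sequence: str) -> str:
    s = sequence.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT/U characters in sequence: {sorted(bad)}")
    return s


def revcomp(sequence: str) -> str:
    return _normalize(sequence).translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    s = _normalize(sequence)
    return (s.count("G") + s.count("C")) / len(s)


def tm_nn(
    sequence: str,
    oligo_conc_M: float = DEFAULT_OLIGO_CONC_M,
    monovalent_salt_M: float = DEFAULT_SALT_M,
) -> float:
    """Nearest-neighbor melting temperature (°C) of a DNA/DNA duplex.

    ``sequence`` is one strand (U is treated as T); the duplex is assumed
    perfectly matched and non-self-complementary with both strands at
    ``oligo_conc_M`` total (CT/4 convention).
    """
    s = _normalize(sequence)
    if len(s) < 8:
        raise ValueError("nearest-neighbor Tm needs >= 8 nt")
    if oligo_conc_M <= 0 or monovalent_salt_M <= 0:
        raise ValueError("concentrations must be positive")
    dh, ds = INITIATION
    for end in (s[0], s[-1]):
        if end in "AT":
            dh += TERMINAL_AT[0]
            ds += TERMINAL_AT[1]
    for i in range(len(s) - 1):
        h, sv = NN_PARAMS[s[i : i + 2]]
        dh += h
        ds += sv
    ds += 0.368 * (len(s) - 1) * math.log(monovalent_salt_M)
    tm_k = dh * 1000.0 / (ds + GAS_CONSTANT * math.log(oligo_conc_M / 4.0))
    return tm_k - 273.15


@dataclass
class TargetWindow:
    """A candidate 40–45-nt probe footprint on a transcript (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int
    sequence: str
    tm: float
    gc: float

    def __len__(self) -> int:
        return self.end - self.start


def _max_homopolymer(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def scan_targets(
    transcript,
    window_len: int | tuple[int, int] = (40, 45),
    tm_target: float = 70.0,
    gc_range: tuple[float, float] = (0.35, 0.65),
    homopolymer_max: int = 4,
    oligo_conc_M: float = DEFAULT_OLIGO_CONC_M,
    monovalent_salt_M: float = DEFAULT_SALT_M,
) -> list[TargetWindow]:
    """Enumerate and rank candidate probe windows on a transcript.

    Every window of the allowed lengths is scored by the full-footprint
    duplex Tm; windows violating the GC range or containing a homopolymer
    run longer than ``homopolymer_max`` are dropped, and survivors are
    ranked by |Tm − tm_target|.  Returns [] (with a warning) when nothing
    passes.
    """
    if hasattr(transcript, "seq"):
        tid, seq = transcript.id, str(transcript.seq)
    else:
        tid, seq = "transcript", str(transcript)
    seq = _normalize(seq)
    lengths = (
        [window_len] if isinstance(window_len, int)
        else list(range(window_len[0], window_len[1] + 1))
    )
    if len(seq) < min(lengths):
        raise ValueError("transcript shorter than the window length")
    out = []
    for L in lengths:
        for start in range(0, len(seq) - L + 1):
            win = seq[start : start + L]
            gc = gc_fraction(win)
            if not gc_range[0] <= gc <= gc_range[1]:
                continue
            if _max_homopolymer(win) > homopolymer_max:
                continue
            tm = tm_nn(win, oligo_conc_M, monovalent_salt_M)
            out.append(TargetWindow(tid, start, start + L, win, tm, gc))
    if not out:
        warnings.warn(
            f"no window on {tid!r} passes the GC/homopolymer filters", stacklevel=2
        )
    out.sort(key=lambda w: (abs(w.tm - tm_target), w.start, len(w)))
    return out


@dataclass
class PadlockProbe:
    """Assembled padlock: 5′arm + backbone + 3′arm.

    The two arms are the reverse complement of the target window, split so
    that revcomp(arm3 + arm5) == window.  The probe's 5′ end is
    phosphorylated; hybridized, it sits immediately 3′ (on the mRNA) of
    the 3′-OH arm end, leaving the sealable nick at ``junction`` (target
    coordinate of the first base covered by the 3′ arm).
    """

    gene: str
    transcript_id: str
    arm5: str
    arm3: str
    backbone: str
    window_start: int
    window_end: int
    junction: int
    tm_arm5: float
    tm_arm3: float

    @property
    def full_sequence(self) -> str:
        return self.arm5 + self.backbone + self.arm3

    @property
    def target_footprint(self) -> str:
        return revcomp(self.arm3 + self.arm5)


def design_padlock(
    window: TargetWindow,
    backbone: str,
    gene: str = "",
    oligo_conc_M: float = DEFAULT_OLIGO_CONC_M,
    monovalent_salt_M: float = DEFAULT_SALT_M,
) -> PadlockProbe:
    """Split a target window into two arms around the backbone.

    A 40-nt window gives two 20-nt arms; odd lengths put the extra base on
    the 3′ arm.  Arms shorter than 15 nt are refused — they cannot reach a
    stable duplex at hybridization temperature.
    """
    if not backbone:
        raise ValueError("backbone must be non-empty")
    rc = revcomp(window.sequence)
    L = len(rc)
    n3 = (L + 1) // 2  # odd → extra base to the 3' arm
    arm3, arm5 = rc[:n3], rc[n3:]
    if min(len(arm3), len(arm5)) < 15:
        raise ValueError("padlock arms must be at least 15 nt")
    probe = PadlockProbe(
        gene=gene or window.transcript_id,
        transcript_id=window.transcript_id,
        arm5=arm5,
        arm3=arm3,
        backbone=_normalize(backbone),
        window_start=window.start,
        window_end=window.end,
        junction=window.start + len(arm5),
        tm_arm5=tm_nn(arm5, oligo_conc_M, monovalent_salt_M),
        tm_arm3=tm_nn(arm3, oligo_conc_M, monovalent_salt_M),
    )
    assert probe.target_footprint == window.sequence
    return probe


@dataclass
class DetectionOligo:
    """3′-labeled, U-substituted readout oligo for one gene's RCA product."""

    gene: str
    sequence: str  # over {A,C,G,U}
    tm: float
    label: str = "3'-fluorophore"


def design_detection_oligo(
    gene_specific_region: str,
    tm_target: float = 56.0,
    gene: str = "",
    label: str = "3'-fluorophore",
    min_len: int = 10,
    oligo_conc_M: float = DEFAULT_OLIGO_CONC_M,
    monovalent_salt_M: float = DEFAULT_SALT_M,
) -> DetectionOligo:
    """Trim a detection oligo out of the padlock's gene-specific region.

    Center-anchored subsequences of every length from ``min_len`` up to
    the full region are scored; the one minimizing |Tm − tm_target| wins
    (ties to the shorter oligo).  T→U substitution is applied last so the
    oligo can be degraded by uracil glycosylase during stripping.  If even
    the best candidate misses the target by more than 5 °C a warning is
    raised and the best effort returned.
    """
    region = _normalize(gene_specific_region)
    if len(region) < 12:
        raise ValueError("gene-specific region must be >= 12 nt")
    best = None
    for L in range(min_len, len(region) + 1):
        start = (len(region) - L) // 2
        cand = region[start : start + L]
        tm = tm_nn(cand, oligo_conc_M, monovalent_salt_M)
        score = abs(tm - tm_target)
        if best is None or score < best[0] - 1e-12:
            best = (score, cand, tm)
    score, seq, tm = best
    if score > 5.0:
        warnings.warn(
            f"detection oligo misses {tm_target} °C by {score:.1f} °C; "
            "returning best effort",
            stacklevel=2,
        )
    return DetectionOligo(gene=gene, sequence=seq.replace("T", "U"), tm=tm,
                          label=label)


def offtarget_scan(
    probe: PadlockProbe,
    transcriptome,
    max_mismatches_per_arm: int = 0,
) -> list[dict]:
    """Local off-target scan of a padlock over a transcript set.

    Reports every locus where both arms would hybridize contiguously and
    adjacently (junction preserved) with at most ``max_mismatches_per_arm``
    mismatches in each arm.  The intended site (same transcript and start)
    is reported with ``intended=True`` and excluded from the off-target
    count callers derive.  This is an exact/near-exact string scan standing
    in for a full alignment-based specificity search.
    """
    records = _load_records(transcriptome)
    if not records:
        raise ValueError("transcriptome is empty")
    footprint = probe.target_footprint
    L = len(footprint)
    n5 = len(probe.arm5)  # target[0:n5] pairs the 5' arm
    fp = np.frombuffer(footprint.encode(), dtype=np.uint8)
    hits = []
    for tid, seq in records:
        s = _normalize(seq)
        if len(s) < L:
            continue
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mism = windows != fp
        mm5 = mism[:, :n5].sum(axis=1)
        mm3 = mism[:, n5:].sum(axis=1)
        ok = (mm5 <= max_mismatches_per_arm) & (mm3 <= max_mismatches_per_arm)
        for pos in np.nonzero(ok)[0]:
            hits.append(
                {
                    "transcript_id": tid,
                    "start": int(pos),
                    "mismatches_arm5": int(mm5[pos]),
                    "mismatches_arm3": int(mm3[pos]),
                    "intended": tid == probe.transcript_id
                    and int(pos) == probe.window_start,
                }
            )
    return hits


def count_offtargets(hits: list[dict]) -> int:
    return sum(1 for h in hits if not h["intended"])


def _load_records(transcriptome) -> list[tuple[str, str]]:
    if isinstance(transcriptome, str):
        return [(r.id, str(r.seq)) for r in SeqIO.parse(transcriptome, "fasta")]
    out = []
    for item in transcriptome:
        if hasattr(item, "seq"):
            out.append((item.id, str(item.seq)))
        else:
            tid, seq = item
            out.append((tid, seq))
    return out
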