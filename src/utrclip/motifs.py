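"""Crosslink-anchored motif statistics.

All sequence work happens in transcript-sense RNA coordinates: minus-strand
genomic windows are reverse-complemented before reaching these functions.
Degenerate motifs such as UGUU(U/A) are expanded to explicit member sets
before any computation.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

RNA = "ACGU"


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MotifSet:
    """A named set of same-length explicit RNA motif members."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty motif set")
        if len({len(m) for m in self.members}) != 1:
            raise ValueError("motif members must share one length")
        for m in self.members:
            if set(m) - set(RNA):
                raise ValueError(f"motif member {m!r} not over ACGU")

    @property
    def length(self) -> int:
        return len(self.members[0])

    @classmethod
    def from_pattern(cls, pattern: str) -> "MotifSet":
        """Expand a degenerate pattern, e.g. ``UGUU(U/A)`` -> {UGUUU, UGUUA}."""
        parts = re.findall(r"\(([^)]+)\)|([ACGU])", dna_to_rna(pattern))
        choices = [grp.split("/") if grp else [ch] for grp, ch in parts]
        members = tuple("".join(p) for p in itertools.product(*choices))
        return cls(name=pattern, members=members)

    def match_at(self, seq: str, start: int) -> bool:
        return 0 <= start <= len(seq) - self.length and seq[start : start + self.length] in self.members


GUU = MotifSet(name="GUU", members=("GUU",))
UGUUUA = MotifSet.from_pattern("UGUU(U/A)")


# ---------------------------------------------------------------------------
# GUU-anchored weighted windows
# ---------------------------------------------------------------------------

@dataclass
class AnchoredWindow:
    sequence: str  # GUU anchor +/- flank, N-padded at UTR edges
    weight: float  # -log10(p) of the source peak; 0 for background


def _padded(seq: str, lo: int, hi: int) -> str:
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(seq))
    return left + seq[max(lo, 0) : min(hi, len(seq))] + right


def nearest_guu_align(
    crosslinks: list[tuple[str, int, float]],
    utr_seqs: dict[str, str],
    search_halfwidth: int = 10,
    flank: int = 10,
    background_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[list[AnchoredWindow], list[AnchoredWindow], int]:
    """Re-center crosslink windows on their nearest GUU.

    ``crosslinks`` are (tx_id, 3' UTR offset, peak p-value) triples. For each
    crosslink the GUU whose start is nearest (ties toward the 5' side) within
    +/- ``search_halfwidth`` nt is anchored and extended by ``flank`` nt on
    each side; the window weight is -log10(p). Background windows are unbound
    GUUs sampled from the same UTRs with weight 0. Returns (foreground,
    background, n_excluded_without_guu).
    """
    rng = np.random.default_rng(np.random.SeedSequence([707, seed]))
    guu_starts: dict[str, list[int]] = {}
    for tx, seq in utr_seqs.items():
        guu_starts[tx] = [m.start() for m in re.finditer("(?=GUU)", seq)]

    xl_positions: dict[str, set[int]] = {}
    for tx, off, _p in crosslinks:
        xl_positions.setdefault(tx, set()).add(off)

    fg: list[AnchoredWindow] = []
    excluded = 0
    for tx, off, p in crosslinks:
        starts = guu_starts.get(tx, [])
        near = [s for s in starts if abs(s - off) <= search_halfwidth]
        if not near:
            excluded += 1
            continue
        best = min(near, key=lambda s: (abs(s - off), s))
        seq = utr_seqs[tx]
        weight = -math.log10(max(p, 1e-300))
        fg.append(AnchoredWindow(_padded(seq, best - flank, best + 3 + flank), weight))
    if excluded:
        log.info("nearest_guu_align: %d crosslink windows without a GUU", excluded)

    # unbound GUUs: start positions whose GUU triplet carries no crosslink
    pool: list[tuple[str, int]] = []
    for tx in sorted(utr_seqs):
        xl = xl_positions.get(tx, set())
        for s in guu_starts[tx]:
            if not any(s + k in xl for k in range(3)):
                pool.append((tx, s))
    n_bg = min(len(pool), int(round(background_ratio * len(fg))))
    bg: list[AnchoredWindow] = []
    if pool and n_bg:
        for i in rng.choice(len(pool), size=n_bg, replace=False):
            tx, s = pool[i]
            bg.append(AnchoredWindow(_padded(utr_seqs[tx], s - flank, s + 3 + flank), 0.0))
    return fg, bg, excluded


def position_weight_stats(
    foreground: list[AnchoredWindow], background: list[AnchoredWindow]
) -> pd.DataFrame:
    """Per-position, per-residue weighted two-proportion z statistics.

    Foreground residue frequencies are weighted by each window's peak weight
    (normalized to mean 1 so a few extreme peaks cannot dominate); background
    windows carry unit weight. Returns a (position x residue) frame of z
    values; the most extreme residue per position is the logo call.
    """
    if not background:
        raise ValueError("degenerate background: no windows")
    if not foreground:
        raise ValueError("no foreground windows")
    L = len(foreground[0].sequence)
    w = np.array([f.weight for f in foreground], dtype=float)
    w = w / w.mean() if w.mean() > 0 else np.ones_like(w)
    n1 = float(len(foreground))
    n2 = float(len(background))
    out = np.zeros((L, 4))
    for j in range(L):
        for r, res in enumerate(RNA):
            fmask = np.array([f.sequence[j] == res for f in foreground], dtype=float)
            fvalid = np.array([f.sequence[j] != "N" for f in foreground], dtype=float)
            p1_den = float((w * fvalid).sum())
            p1 = float((w * fmask).sum()) / p1_den if p1_den else 0.0
            bmask = [b.sequence[j] == res for b in background]
            bvalid = sum(b.sequence[j] != "N" for b in background)
            p2 = sum(bmask) / bvalid if bvalid else 0.0
            pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
            se = math.sqrt(max(pooled * (1 - pooled), 0.0) * (1 / n1 + 1 / n2))
            out[j, r] = (p1 - p2) / se if se > 0 else 0.0
    return pd.DataFrame(out, columns=list(RNA))


# ---------------------------------------------------------------------------
# offset profiles and site fractions
# ---------------------------------------------------------------------------

def motif_offset_profile(
    motif: MotifSet,
    crosslinks: list[tuple[str, int]],
    utr_seqs: dict[str, str],
    offset_range: tuple[int, int] = (-50, 50),
    background_per_utr: tuple[int, int] = (10, 20),
    seed: int = 0,
) -> pd.DataFrame:
    """Motif start frequency at each offset from the crosslink nucleotide,
    normalized to random positions drawn from the same bound 3' UTRs.

    Returns offset, observed, background, enrichment.
    """
    lo, hi = offset_range
    if motif.length > hi - lo + 1:
        raise ValueError("motif longer than the scanned window")
    rng = np.random.default_rng(np.random.SeedSequence([808, seed]))

    def freq_at(points: list[tuple[str, int]]) -> np.ndarray:
        hits = np.zeros(hi - lo + 1)
        for tx, off in points:
            seq = utr_seqs[tx]
            for k, o in enumerate(range(lo, hi + 1)):
                if motif.match_at(seq, off + o):
                    hits[k] += 1
        return hits / max(len(points), 1)

    observed = freq_at(crosslinks)
    bound_txs = sorted({tx for tx, _ in crosslinks})
    bg_points: list[tuple[str, int]] = []
    for tx in bound_txs:
        n = int(rng.integers(background_per_utr[0], background_per_utr[1], endpoint=True))
        L = len(utr_seqs[tx])
        for p in rng.integers(0, L, size=min(n, L)).tolist():
            bg_points.append((tx, p))
    background = freq_at(bg_points)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(background > 0, observed / background, np.nan)
    return pd.DataFrame(
        {
            "offset": np.arange(lo, hi + 1),
            "observed": observed,
            "background": background,
            "enrichment": enrich,
        }
    )


def site_motif_fraction(
    motif: MotifSet,
    site_representatives: list[tuple[str, int]],
    utr_seqs: dict[str, str],
    halfwidth: int = 10,
) -> float:
    """Percentage of binding sites whose representative nucleotide +/-
    ``halfwidth`` nt contains a motif member's 5' start. Windows overrunning
    the UTR are clipped."""
    if not site_representatives:
        return 0.0
    n_hit = 0
    clipped = 0
    for tx, rep in site_representatives:
        seq = utr_seqs[tx]
        lo = rep - halfwidth
        hi = rep + halfwidth
        if lo < 0 or hi >= len(seq):
            clipped += 1
        lo = max(lo, 0)
        hi = min(hi, len(seq) - 1)
        if any(motif.match_at(seq, s) for s in range(lo, hi + 1)):
            n_hit += 1
    if clipped:
        log.info("site_motif_fraction: clipped %d windows at UTR bounds", clipped)
    return 100.0 * n_hit / len(site_representatives)


# ---------------------------------------------------------------------------
# analytic expected fraction (0-order background)
# ---------------------------------------------------------------------------

def expected_motif_fraction(
    motif: MotifSet, freqs: dict[str, float], window_len: int = 21
) -> float:
    """Exact probability that an i.i.d. window of ``window_len`` nt contains
    at least one motif member, by dynamic programming over the Aho-Corasick
    automaton of the member set (0-order background model)."""
    total = sum(freqs.get(b, 0.0) for b in RNA)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("nucleotide frequencies must sum to 1")
    if window_len < motif.length:
        return 0.0
    # states: prefixes of members; transition to longest suffix that is a prefix
    prefixes = {""}
    for m in motif.members:
        for k in range(1, len(m) + 1):
            prefixes.add(m[:k])
    states = sorted(prefixes, key=lambda s: (len(s), s))
    idx = {s: i for i, s in enumerate(states)}
    members = set(motif.members)

    def step(state: str, ch: str) -> tuple[int, bool]:
        s = state + ch
        if any(s.endswith(m) for m in members):
            return -1, True
        while s not in idx:
            s = s[1:]
        return idx[s], False

    trans = {
        (i, ch): step(s, ch) for i, s in enumerate(states) for ch in RNA
    }
    prob = np.zeros(len(states))
    prob[idx[""]] = 1.0
    absorbed = 0.0
    for _ in range(window_len):
        nxt = np.zeros(len(states))
        for i in range(len(states)):
            if prob[i] == 0.0:
                continue
            for ch in RNA:
                j, hit = trans[(i, ch)]
                mass = prob[i] * freqs.get(ch, 0.0)
                if hit:
                    absorbed += mass
                else:
                    nxt[j] += mass
        prob = nxt
    return float(absorbed)


# ---------------------------------------------------------------------------
# rank-sum enrichment against shuffled controls
# ---------------------------------------------------------------------------

def foreground_halfwidth(motif_len: int) -> int:
    """Crosslink-window half-width sized so the motif's UU core can overlap
    the crosslink: +/-2 nt for 3-4-nt motifs, +/-(len-2) for longer ones."""
    return max(2, motif_len - 2)


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)


def _avg_score(seq: str, motif: MotifSet) -> float:
    n_pos = len(seq) - motif.length + 1
    if n_pos < 1:
        return 0.0
    return sum(motif.match_at(seq, s) for s in range(n_pos)) / n_pos


def ranksum_motif_enrichment(
    foreground: list[str],
    motif: MotifSet,
    n_shuffles: int = 1,
    seed: int = 0,
    n_motifs_tested: int = 1,
) -> tuple[float, float, float]:
    """Wilcoxon rank-sum enrichment of a motif in foreground windows against
    per-sequence mononucleotide shuffles.

    Per-sequence score is the average motif-match indicator over all window
    positions. Returns (U statistic, raw one-sided p, Bonferroni-adjusted p).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not foreground:
        raise ValueError("no foreground sequences")
    rng = np.random.default_rng(np.random.SeedSequence([909, seed]))
    fg_scores = [_avg_score(s, motif) for s in foreground]
    ctrl_scores = [
        _avg_score(mononucleotide_shuffle(s, rng), motif)
        for s in foreground
        for _ in range(n_shuffles)
    ]
    stat, p = stats.mannwhitneyu(fg_scores, ctrl_scores, alternative="greater")
    return float(stat), float(p), float(min(1.0, p * n_motifs_tested))
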