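"""In-house motif discovery (EM, oops/zoops) and PWM scanning with exact
score-distribution p-values; promoter spacer lengths; TEP subcategory
classification.

The EM discoverer is a minimal stand-in for MEME's oops ("one occurrence per
sequence") and zoops ("zero or one") modes: responsibilities over site
offsets (plus a no-site option under zoops) are iterated to convergence from
multiple seeded starts, and the highest-likelihood PWM wins.  Scanning
mirrors FIMO's construction: a hit is a position whose log-odds score has an
exact p-value, computed by dynamic programming over the discretized score
distribution under the background model, below the threshold.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .fold import fold_energy

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_IDX_BASE = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX[c] for c in seq.upper()], dtype=np.int64)


@dataclass
class PWM:
    probs: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray  # length 4
    sites: list = field(default_factory=list)  # (seq index, offset)
    log_likelihood: float = float("-inf")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_IDX_BASE[i] for i in self.probs.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Sum over columns of 2 - H(column), bits."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())

    def to_dict(self) -> dict:
        return {"probs": self.probs.tolist(),
                "background": self.background.tolist(),
                "sites": list(map(list, self.sites)),
                "log_likelihood": self.log_likelihood}


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_windows(
    anchors: list,
    annotation,
    from_off: int,
    to_off: int,
    chrom: str = "chr1",
) -> list:
    """Strand-aware fixed-width sequences around anchors ``(pos, strand)``.

    Offsets are in transcription direction relative to the anchor (offset 0
    = the anchor base itself); minus-strand windows are reverse-complemented.
    Out-of-bounds anchors are dropped with a warning.  Returns a list
    parallel to the surviving anchors: ``(anchor, sequence)``.
    """
    if to_off < from_off:
        raise ValueError("to_off must be >= from_off")
    L = annotation.chrom_length(chrom)
    out = []
    dropped = 0
    for pos, strand in anchors:
        if strand == "+":
            lo, hi = pos + from_off, pos + to_off
        else:
            lo, hi = pos - to_off, pos - from_off
        if lo < 1 or hi > L:
            dropped += 1
            continue
        out.append(((pos, strand), annotation.sequence(chrom, lo, hi, strand)))
    if dropped:
        print(f"[motifs] {dropped} anchor(s) out of bounds, dropped", file=sys.stderr)
    return out


# ---------------------------------------------------------------------------
# EM motif discovery
# ---------------------------------------------------------------------------

def _background_freqs(codes_list) -> np.ndarray:
    counts = np.zeros(4)
    for c in codes_list:
        counts += np.bincount(c, minlength=4)
    return counts / counts.sum()


def discover_motif(
    sequences: list,
    width: int,
    mode: str = "oops",
    seed: int = 0,
    n_starts: int = 20,
    n_iter: int = 60,
    pseudocount: float = 0.25,
    zoops_prior: float = 0.5,
) -> PWM:
    """EM motif discovery over equal-role sequences.

    oops: exactly one site per sequence; zoops: at most one, with prior
    probability ``zoops_prior`` that a sequence contains a site.  Runs
    ``n_starts`` seeded restarts and returns the highest-likelihood PWM with
    its maximum-responsibility site list.
    """
    if mode not in ("oops", "zoops"):
        raise ValueError("mode must be 'oops' or 'zoops'")
    if len(sequences) < 10:
        raise ValueError("at least 10 sequences are required")
    codes = [_encode(s) for s in sequences]
    if min(len(c) for c in codes) < width:
        raise ValueError("width exceeds the shortest sequence")
    bg = _background_freqs(codes)
    log_bg = np.log(bg)
    # per-sequence window views and background log-likelihood sums, shared
    # across restarts and iterations
    wins = [np.lib.stride_tricks.sliding_window_view(c, width) for c in codes]
    bg_win = [log_bg[w].sum(axis=1) for w in wins]
    bg_full = sum(log_bg[c].sum() for c in codes)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        probs = _init_pwm(rng, codes, width, pseudocount)
        for _ in range(n_iter):
            probs, ll = _em_step(wins, bg_win, bg_full, probs, width, mode,
                                 pseudocount, zoops_prior)
        if best is None or ll > best.log_likelihood:
            sites = _map_sites(wins, bg_win, probs, mode, zoops_prior)
            best = PWM(probs, bg, sites, ll)
    return best


def _init_pwm(rng, codes, width, pseudocount):
    i = rng.integers(0, len(codes))
    j = rng.integers(0, len(codes[i]) - width + 1)
    seed_site = codes[i][j : j + width]
    probs = np.full((width, 4), 0.1)
    probs[np.arange(width), seed_site] = 0.7
    return probs / probs.sum(axis=1, keepdims=True)


def _site_lr(win, bg_sum, log_probs):
    """Log-ratio of site-at-offset vs background, all offsets at once."""
    width = log_probs.shape[0]
    return log_probs[np.arange(width)[None, :], win].sum(axis=1) - bg_sum


def _em_step(wins, bg_win, bg_full, probs, width, mode, pseudocount, zoops_prior):
    log_probs = np.log(np.clip(probs, 1e-12, 1.0))
    new = np.full((width, 4), pseudocount)
    total_ll = bg_full
    cols = np.arange(width)[:, None]
    for win, bg_sum in zip(wins, bg_win):
        n = win.shape[0]
        lr = _site_lr(win, bg_sum, log_probs)
        m = lr.max()
        if mode == "oops":
            resp = np.exp(lr - m)
            s = resp.sum()
            resp /= s
            total_ll += m + np.log(s / n)
        else:
            site_term = (zoops_prior / n) * np.exp(lr - m)
            denom = site_term.sum() + (1 - zoops_prior) * np.exp(-m)
            resp = site_term / denom
            total_ll += m + np.log(denom)
        np.add.at(new, (cols, win.T), resp[None, :])
    new /= new.sum(axis=1, keepdims=True)
    return new, total_ll


def _map_sites(wins, bg_win, probs, mode, zoops_prior):
    log_probs = np.log(np.clip(probs, 1e-12, 1.0))
    sites = []
    for i, (win, bg_sum) in enumerate(zip(wins, bg_win)):
        n = win.shape[0]
        lr = _site_lr(win, bg_sum, log_probs)
        j_best = int(lr.argmax())
        if mode == "zoops":
            # keep the site only when it beats the no-site alternative
            if zoops_prior / n * np.exp(lr[j_best]) <= (1 - zoops_prior):
                continue
        sites.append((i, j_best))
    return sites


# ---------------------------------------------------------------------------
# scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    seq_index: int
    offset: int  # 0-based start within the scanned sequence
    score: float
    p: float


_SCALE = 0.005  # log-odds discretization (bits per bin)
_FLOOR = -30.0  # scores clipped here; beyond-rare mismatch penalty


def _score_matrix(pwm: PWM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lod = np.log2(pwm.probs / pwm.background[None, :])
    return np.clip(lod, _FLOOR, None)


def score_distribution(pwm: PWM):
    """Exact distribution of the log-odds score under the background model.

    Returns ``(offset, probs)``: integer-bin DP convolution over columns;
    bin b corresponds to score (b + offset) * _SCALE.
    """
    lod = np.round(_score_matrix(pwm) / _SCALE).astype(int)
    # DP: point mass at 0, shifted and mixed one column at a time
    dist = np.array([1.0])
    offset = 0
    for col in range(pwm.width):
        cmin, cmax = lod[col].min(), lod[col].max()
        new = np.zeros(len(dist) + (cmax - cmin))
        for b in range(4):
            sh = lod[col, b] - cmin
            new[sh : sh + len(dist)] += pwm.background[b] * dist
        dist = new
        offset += cmin
    return offset, dist


def scan_pwm(pwm: PWM, sequences: list, p_threshold: float = 0.01) -> list:
    """Log-odds scan; hits are positions with exact p < ``p_threshold``.

    p(s) = P(score >= s) under the background model, computed on the
    discretized score distribution (bin width ``_SCALE`` bits).
    """
    lod_int = np.round(_score_matrix(pwm) / _SCALE).astype(int)
    offset, dist = score_distribution(pwm)
    tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])

    def pvalue(int_score: int) -> float:
        b = int_score - offset
        if b < 0:
            return 1.0
        if b >= len(dist):
            return 0.0
        return float(min(tail[b], 1.0))

    hits = []
    w = pwm.width
    for i, s in enumerate(sequences):
        code = _encode(s)
        for j in range(len(code) - w + 1):
            sc = int(lod_int[np.arange(w), code[j : j + w]].sum())
            p = pvalue(sc)
            if p < p_threshold:
                hits.append(MotifHit(i, j, sc * _SCALE, p))
    return hits


def spacer_lengths(minus35_hits: dict, minus10_hits: dict) -> dict:
    """Nucleotides strictly between the -35 motif's 3' end and the -10
    motif's 5' start, per promoter.

    Inputs map promoter id -> (start, end) of each motif in common promoter
    coordinates (0-based closed).  Overlapping motifs yield a negative
    spacer (flagged downstream); adjacent motifs yield 0.
    """
    out = {}
    for pid, (s35, e35) in minus35_hits.items():
        if pid not in minus10_hits:
            continue
        s10, _e10 = minus10_hits[pid]
        out[pid] = s10 - e35 - 1
    return out


# ---------------------------------------------------------------------------
# TEP subcategory classification
# ---------------------------------------------------------------------------

def classify_tep_subcategory(
    dG: float,
    has_motif_hit: bool,
    dg_split: float = -25.0,
) -> str:
    """Motif > structured > unstructured precedence.

    A TEP carrying the conserved motif is 'motif' regardless of its folding
    energy; otherwise the -40..+1 window's minimum free energy decides:
    below ``dg_split`` kcal/mol structured, else unstructured.  The split is
    folding-engine-specific and therefore configurable.
    """
    if has_motif_hit:
        return "motif"
    return "structured_non_motif" if dG < dg_split else "unstructured_non_motif"


def tep_fold_energies(teps: list, annotation, fold_fn=fold_energy,
                      from_off: int = -40, to_off: int = 1) -> dict:
    """Fold the -40..+1 window of each TEP; returns position -> FoldResult."""
    windows = extract_windows([(t.position, t.strand) for t in teps],
                              annotation, from_off, to_off)
    return {pos: fold_fn(seq) for (pos, strand), seq in windows}
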