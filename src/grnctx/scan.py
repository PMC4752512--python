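"""MATCH-style promoter scanning with core/matrix similarity scores.

Every window of motif length in a promoter sequence (and, by default, its
reverse complement) is scored against a PWM.  The matrix similarity score is
the information-weighted, min–max-normalized match

    MSS = (Current − Min) / (Max − Min),
    Current = sum_i I(i) * f(i, s_i),
    Max/Min = the same sums with the per-position max/min frequency,

and the core similarity score (CSS) is the identical quantity restricted to
the 5-position high-information core.  A site is retained when both scores
reach their thresholds (0.90 by default).  Promoter windows are −2000/+1000
around the transcription start site by default; hit offsets are 0-based,
half-open, relative to window start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from grnctx.network import GRN, Interaction
from grnctx.pwm import ALPHABET, PWM, reverse_complement

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A,C,G,T -> 0..3; anything else -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning thresholds and window geometry."""

    css_min: float = 0.90
    mss_min: float = 0.90
    window: tuple[int, int] = (2000, 1000)  # (upstream, downstream) of TSS
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("css_min", "mss_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.01:  # 1.01 is a legal "unsatisfiable" setting
                if not 0.0 <= v:
                    raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class SiteHit:
    """A retained binding-site prediction on a promoter window."""

    tf_id: str
    gene_id: str
    offset: int  # 0-based start relative to window start, forward coordinates
    strand: str  # '+' or '-'
    css: float
    mss: float


def _span_scores(pwm: PWM, codes: np.ndarray, span: slice) -> np.ndarray:
    """Normalized similarity over `span` positions for all windows in `codes`
    (windows × motif-length integer matrix; assumes all codes valid)."""
    freq = pwm.freq[span]
    info = pwm.info[span]
    weights = info[:, None] * freq  # (l, 4)
    sub = codes[:, span]
    positions = np.arange(sub.shape[1])
    current = weights[positions[None, :], sub].sum(axis=1)
    vmax = float((info * freq.max(axis=1)).sum())
    vmin = float((info * freq.min(axis=1)).sum())
    if vmax - vmin <= 0.0:
        return np.ones(len(sub))
    return np.clip((current - vmin) / (vmax - vmin), 0.0, 1.0)


def _score_windows(pwm: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(css, mss) arrays for a (windows, L) code matrix."""
    mss = _span_scores(pwm, codes, slice(0, len(pwm)))
    css = _span_scores(pwm, codes, pwm.core_slice)
    return css, mss


def score_window(pwm: PWM, seq: str) -> tuple[float, float]:
    """Score a single window of exactly motif length; returns (css, mss).

    Raises on length mismatch or non-ACGT characters.
    """
    if len(seq) != len(pwm):
        raise ValueError(f"window length {len(seq)} != motif length {len(pwm)}")
    codes = encode(seq)
    if np.any(codes < 0):
        raise ValueError(f"non-ACGT character in window {seq!r}")
    css, mss = _score_windows(pwm, codes[None, :])
    return float(css[0]), float(mss[0])


def _scan_strand(pwm: PWM, codes: np.ndarray, cfg: ScanConfig) -> list[tuple[int, float, float]]:
    L = len(pwm)
    if len(codes) < L:
        return []
    windows = sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("skipped %d windows containing non-ACGT characters", n_skipped)
    windows = windows[valid]
    if not len(windows):
        return []
    css, mss = _score_windows(pwm, windows)
    keep = (css >= cfg.css_min) & (mss >= cfg.mss_min)
    offsets = np.flatnonzero(valid)[keep]
    return list(zip(offsets.tolist(), css[keep].tolist(), mss[keep].tolist()))


def scan_promoter(
    pwm: PWM, seq: str, cfg: ScanConfig = ScanConfig(), gene_id: str = ""
) -> list[SiteHit]:
    """Slide the PWM over every window of a promoter sequence.

    The reverse complement is scanned too when ``cfg.scan_both_strands``;
    minus-strand hits are mapped back to forward window-start coordinates.
    Hits with css >= css_min and mss >= mss_min are returned sorted by
    (offset, strand).  Windows containing non-ACGT characters are skipped.
    """
    codes = encode(seq)
    hits = [
        SiteHit(pwm.tf_id, gene_id, off, "+", css, mss)
        for off, css, mss in _scan_strand(pwm, codes, cfg)
    ]
    if cfg.scan_both_strands:
        rc_codes = encode(reverse_complement(seq))
        n, L = len(seq), len(pwm)
        hits += [
            SiteHit(pwm.tf_id, gene_id, n - off - L, "-", css, mss)
            for off, css, mss in _scan_strand(pwm, rc_codes, cfg)
        ]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_library(
    pwms: list[PWM], promoters: dict[str, str], cfg: ScanConfig = ScanConfig()
) -> list[SiteHit]:
    """Scan every promoter with every PWM in the library."""
    hits: list[SiteHit] = []
    for gene_id in sorted(promoters):
        seq = promoters[gene_id]
        for pwm in pwms:
            hits.extend(scan_promoter(pwm, seq, cfg, gene_id=gene_id))
    return hits


def build_upstream_network(hits: list[SiteHit]) -> GRN:
    """Collapse retained binding sites into an unsigned, directed TF→gene
    network: one edge per (tf, gene) pair with at least one hit."""
    grn = GRN()
    for tf_id, gene_id in sorted({(h.tf_id, h.gene_id) for h in hits}):
        grn.add(Interaction(tf_id, gene_id, "?", frozenset({"tfbs"})))
    return grn


def write_hits(hits: list[SiteHit], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "tf": h.tf_id,
                "gene": h.gene_id,
                "offset": h.offset,
                "strand": h.strand,
                "css": round(h.css, 6),
                "mss": round(h.mss, 6),
            }
            for h in hits
        ],
        columns=["tf", "gene", "offset", "strand", "css", "mss"],
    ).to_csv(path, sep="\t", index=False)
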