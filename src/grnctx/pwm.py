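"""Position weight matrices and their information-vector scoring substrate.

A PWM is a positions × {A,C,G,T} matrix of base frequencies describing a
transcription factor's binding motif.  Scoring weights each position by its
information content

    I(i) = sum_b f(i,b) * ln(4 * f(i,b)),      with 0*ln(0) := 0,

which is ln(4) minus the Shannon entropy of the position: 0 for an
uninformative (uniform) position, ln(4) for a fully conserved one.  The
5-position *core* is the window of 5 consecutive positions with maximal
summed information (leftmost on ties); it drives the core similarity score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
CORE_WIDTH = 5

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_vector(freq: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Per-position information content I(i) of a frequency matrix.

    Parameters
    ----------
    freq : (L, 4) array of per-position base frequencies, rows summing to 1.
    tol : tolerance on the row-sum check.

    Returns
    -------
    (L,) array with I(i) in [0, ln 4].
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 4:
        raise ValueError(f"frequency matrix must be (L, 4), got {freq.shape}")
    if np.any(freq < 0):
        raise ValueError("frequency matrix has negative entries")
    rowsums = freq.sum(axis=1)
    bad = np.abs(rowsums - 1.0) > tol
    if np.any(bad):
        raise ValueError(
            f"rows {np.flatnonzero(bad).tolist()} do not sum to 1 (sums {rowsums[bad].tolist()})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log(4.0 * freq), 0.0)
    info = terms.sum(axis=1)
    # entropy bound guarantees >= 0 up to rounding
    return np.maximum(info, 0.0)


def _core_start(info: np.ndarray) -> int:
    """Start index of the maximal-information 5-window; leftmost on ties."""
    if info.size < CORE_WIDTH:
        raise ValueError(f"motif shorter than the {CORE_WIDTH}-position core")
    window_sums = np.convolve(info, np.ones(CORE_WIDTH), mode="valid")
    # exact leftmost-tie behaviour despite float noise
    best = window_sums.max()
    return int(np.flatnonzero(window_sums >= best - 1e-12)[0])


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with its derived information vector and core.

    Attributes
    ----------
    tf_id : transcription factor identifier.
    freq : (L, 4) frequency matrix over A, C, G, T.
    info : per-position information vector (derived).
    core_start : start of the 5-position high-information core (derived).
    """

    tf_id: str
    freq: np.ndarray
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if len(freq) < CORE_WIDTH:
            raise ValueError(
                f"PWM {self.tf_id!r} has length {len(freq)}; the core needs "
                f"{CORE_WIDTH} consecutive positions"
            )
        info = information_vector(freq)
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "info", info)
        object.__setattr__(self, "core_start", _core_start(info))

    def __len__(self) -> int:
        return len(self.freq)

    @property
    def consensus(self) -> str:
        """Most frequent base at each position (first of A,C,G,T on ties)."""
        return "".join(ALPHABET[b] for b in np.argmax(self.freq, axis=1))

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start, self.core_start + CORE_WIDTH)


# ---------------------------------------------------------------------------
# TRANSFAC matrix format I/O (via Bio.motifs)
# ---------------------------------------------------------------------------

_COUNT_SCALE = 1000.0


def write_transfac(pwms: list[PWM], path) -> None:
    """Write PWMs as TRANSFAC matrices (ID line, per-position A C G T counts,
    ``//`` terminator).  Frequencies are scaled to counts-per-1000."""
    from Bio.motifs import transfac

    records = []
    for pwm in pwms:
        counts = {
            base: [round(float(pwm.freq[i, j] * _COUNT_SCALE), 3) for i in range(len(pwm))]
            for j, base in enumerate(ALPHABET)
        }
        motif = transfac.Motif(alphabet="GATC", counts=counts)
        motif["ID"] = pwm.tf_id
        motif["AC"] = pwm.tf_id
        records.append(motif)
    text = transfac.write(records)
    with open(path, "w") as handle:
        handle.write(text)


def read_transfac(path) -> list[PWM]:
    """Read a TRANSFAC matrix library; counts are row-normalized to
    frequencies on load."""
    from Bio import motifs as bio_motifs

    if hasattr(path, "read"):
        handle: io.TextIOBase = path
        records = bio_motifs.parse(handle, "TRANSFAC")
    else:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "TRANSFAC")
    pwms = []
    for record in records:
        tf_id = record.get("ID") or record.get("AC")
        if not tf_id:
            raise ValueError("TRANSFAC record without ID/AC line")
        counts = np.array(
            [[record.counts[base][i] for base in ALPHABET] for i in range(record.length)],
            dtype=float,
        )
        rowsums = counts.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError(f"matrix {tf_id}: position with zero total count")
        pwms.append(PWM(tf_id=str(tf_id), freq=counts / rowsums[:, None]))
    return pwms
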