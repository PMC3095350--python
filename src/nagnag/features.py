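"""The 31-feature representation of a tandem acceptor.

28 positional nucleotide features (last 3 nt of the upstream exon, the
20 intronic nt immediately upstream of the NAGNAG, the two N wildcards,
and 3 nt downstream of the motif), the Y-content (pyrimidine count of
the 20-nt upstream window, a polypyrimidine-tract strength proxy), and
two acceptor-strength scores from a position-specific log-odds model —
one per alternative junction.

The acceptor scorer is a 23-position PWM spanning -20..+3 around a 3'
splice junction (the acceptor AG occupies positions -2/-1), trained on
constitutive acceptor windows with an add-one pseudocount against
genome background frequencies, scores in bits.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import SENTINEL, ContextSequence, NagnagSite

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PWM_WINDOW = 23  # positions -20..-1 (intronic, AG at -2/-1) and +1..+3 (exonic)

# 0-based offsets of the two 23-nt acceptor windows inside the 49-mer.
# Proximal junction = the G at context position 36 (1-based); distal at 39.
_WINDOW_SLICE = {"proximal": (16, 39), "distal": (19, 42)}

# 0-based context positions of the 28 positional features.
POSITIONAL_FEATURES: dict[str, int] = {}
for _i in range(3):
    POSITIONAL_FEATURES[f"exon_m{3 - _i}"] = _i
for _i in range(20):
    POSITIONAL_FEATURES[f"up_m{20 - _i}"] = 13 + _i
POSITIONAL_FEATURES["n1"] = 33
POSITIONAL_FEATURES["n2"] = 36
for _i in range(3):
    POSITIONAL_FEATURES[f"down_p{_i + 1}"] = 39 + _i

NUMERIC_FEATURES = ("y_content", "score_e", "score_i")
FEATURE_NAMES = tuple(POSITIONAL_FEATURES) + NUMERIC_FEATURES  # 31 predictors

#: the reduced transfer view: the two Ns, the two positions immediately
#: upstream of the motif and the position immediately downstream
REDUCED_FEATURES = ("n1", "n2", "up_m1", "up_m2", "down_p1")

_Y_WINDOW = slice(13, 33)  # the 20 nt immediately 5' of the motif


class SentinelError(ValueError):
    """A pad sentinel fell inside a window required for a feature."""


def compute_y_content(context: ContextSequence) -> int:
    """Number of pyrimidines (C/T) in the 20 nt upstream of the NAGNAG."""
    window = context.seq49[_Y_WINDOW]
    if SENTINEL in window:
        raise SentinelError(f"{context.site_id}: sentinel in Y-content window")
    return sum(1 for b in window if b in "CT")


def acceptor_window(context: ContextSequence, which: str) -> str:
    """The 23-nt scoring window for the proximal or distal junction."""
    lo, hi = _WINDOW_SLICE[which]
    return context.seq49[lo:hi]


@dataclass
class AcceptorPwm:
    """Position-specific log2-odds acceptor model over a 23-nt window."""

    logodds: np.ndarray  # (23, 4), bits
    background: np.ndarray  # (4,)
    pseudocount: float
    n_training: int

    def to_json(self, path) -> None:
        payload = {
            "window": PWM_WINDOW,
            "bases": BASES,
            "logodds": self.logodds.tolist(),
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "n_training": self.n_training,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AcceptorPwm":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            logodds=np.asarray(d["logodds"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            pseudocount=float(d["pseudocount"]),
            n_training=int(d["n_training"]),
        )


def _background_vector(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    if isinstance(background, Mapping):
        vec = np.array([background[b] for b in BASES], dtype=float)
    else:
        vec = np.asarray(background, dtype=float)
    if vec.shape != (4,) or not np.isclose(vec.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    return vec


def train_acceptor_pwm(
    windows: Sequence[str], background=None, pseudocount: float = 1.0
) -> AcceptorPwm:
    """Fit the log-odds acceptor model from constitutive 23-nt windows."""
    windows = [w.upper() for w in windows]
    if not windows:
        raise ValueError("cannot train an acceptor model on zero windows")
    if len(windows) < 50:
        log.warning("training acceptor model on only %d windows", len(windows))
    bg = _background_vector(background)
    counts = np.zeros((PWM_WINDOW, 4))
    for w in windows:
        if len(w) != PWM_WINDOW:
            raise ValueError(f"window {w!r} is not {PWM_WINDOW} nt")
        for pos, base in enumerate(w):
            if base in _BASE_INDEX:
                counts[pos, _BASE_INDEX[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    return AcceptorPwm(
        logodds=np.log2(probs / bg),
        background=bg,
        pseudocount=pseudocount,
        n_training=len(windows),
    )


def score_acceptor(pwm: AcceptorPwm, context: ContextSequence | str, which: str = "proximal"):
    """Sum of per-position log2 odds over the junction's 23-nt window.

    Returns ``None`` when a sentinel letter falls inside the window.
    """
    window = context if isinstance(context, str) else acceptor_window(context, which)
    if len(window) != PWM_WINDOW:
        raise ValueError(f"scoring window must be {PWM_WINDOW} nt")
    if SENTINEL in window:
        return None
    return float(sum(pwm.logodds[i, _BASE_INDEX[b]] for i, b in enumerate(window)))


def extract_feature_vector(
    site: NagnagSite, context: ContextSequence, pwm: AcceptorPwm
) -> dict:
    """All 31 predictors for one site, as an ordered mapping.

    Raises :class:`SentinelError` when any of the 28 positional feature
    slots holds a pad sentinel; such sites are excluded from training
    and prediction.
    """
    seq = context.seq49
    vec: dict = {}
    for name, pos in POSITIONAL_FEATURES.items():
        letter = seq[pos]
        if letter == SENTINEL:
            raise SentinelError(f"{site.site_id}: sentinel at feature {name}")
        vec[name] = letter
    assert vec["n1"] == site.motif[0] and vec["n2"] == site.motif[3]
    vec["y_content"] = compute_y_content(context)
    vec["score_e"] = score_acceptor(pwm, context, "proximal")
    vec["score_i"] = score_acceptor(pwm, context, "distal")
    return vec


def extract_features(
    sites: Sequence[NagnagSite],
    contexts: Mapping[str, ContextSequence],
    pwm: AcceptorPwm,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for many sites; returns (frame, excluded site ids)."""
    rows, index, excluded = [], [], []
    for site in sites:
        try:
            rows.append(extract_feature_vector(site, contexts[site.site_id], pwm))
            index.append(site.site_id)
        except SentinelError as exc:
            log.info("excluded from feature extraction: %s", exc)
            excluded.append(site.site_id)
    frame = pd.DataFrame(rows, index=pd.Index(index, name="site_id"),
                         columns=list(FEATURE_NAMES))
    return frame, excluded


def reduced_view(frame: pd.DataFrame) -> pd.DataFrame:
    """Restrict a feature matrix to the 5-feature transfer view."""
    return frame[list(REDUCED_FEATURES)]


@dataclass
class CompositionMatrix:
    """Per-position base frequencies over the 49 context positions."""

    freqs: pd.DataFrame  # 49 rows x 4 base columns
    n: int
    subset: str = "all"


def composition_matrix(
    contexts: Iterable[ContextSequence],
    labels: Mapping[str, str] | None = None,
    subset: str | None = None,
) -> CompositionMatrix:
    """Base-composition matrix (the numbers behind a sequence logo).

    ``subset`` restricts to contexts whose label equals it (e.g. "EI").
    Sentinel letters are ignored position-wise; rows are normalised over
    the counted letters.
    """
    counts = np.zeros((49, 4))
    n = 0
    for c in contexts:
        if subset is not None:
            if labels is None or labels.get(c.site_id) != subset:
                continue
        n += 1
        for pos, base in enumerate(c.seq49):
            if base in _BASE_INDEX:
                counts[pos, _BASE_INDEX[base]] += 1
    if n == 0:
        raise ValueError(f"no contexts in subset {subset!r}")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    frame = pd.DataFrame(freqs, columns=list(BASES))
    frame.index.name = "position"
    return CompositionMatrix(freqs=frame, n=n, subset=subset or "all")
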