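"""Optional loader for BCI Competition III Dataset IVa MAT containers.

The published layout stores a continuous multichannel signal ``cnt``
(samples x channels, int16 in units of 0.1 microvolt in the official files),
a marker structure ``mrk`` with cue positions ``pos`` (samples) and class
codes ``y`` (1 = right hand, 2 = right foot, NaN = unlabeled competition
test trials), and an info structure ``nfo`` with the sampling rate ``fs``
and channel labels ``clab``.  The loader cuts fixed-length epochs at the cue
markers; unlabeled trials are dropped.  None of the build or test machinery
requires these files — a matching writer exists so synthetic trial sets can
round-trip through the same container.
"""

from __future__ import annotations

import numpy as np
from scipy import io as spio

from .containers import FOOT, HAND, TrialSet

__all__ = ["load_competition_trials", "save_competition_trials"]

_CLASS_CODES = {1: HAND, 2: FOOT}


def _field(struct: np.ndarray, name: str, context: str):
    try:
        return struct[name].item() if struct[name].shape == (1, 1) else struct[name]
    except (KeyError, ValueError, IndexError) as err:
        raise ValueError(f"malformed {context}: missing field '{name}'") from err


def load_competition_trials(path: str, epoch_s: float = 3.5) -> TrialSet:
    """Epoch a competition-format MAT file into a labeled sensor TrialSet."""
    mat = spio.loadmat(path, squeeze_me=False, struct_as_record=True)
    for key in ("cnt", "mrk", "nfo"):
        if key not in mat:
            raise ValueError(f"malformed competition file: missing variable '{key}'")
    cnt = np.asarray(mat["cnt"])
    if np.issubdtype(cnt.dtype, np.integer):
        cnt = cnt.astype(float) * 0.1e-6  # official int16 files store 0.1 uV units
    else:
        cnt = cnt.astype(float)
    mrk = mat["mrk"][0, 0]
    nfo = mat["nfo"][0, 0]
    fs = float(np.squeeze(_field(nfo, "fs", "nfo structure")))
    clab = _field(nfo, "clab", "nfo structure")
    labels_raw = np.atleast_1d(np.squeeze(np.asarray(_field(mrk, "y", "marker structure"), dtype=float)))
    positions = np.atleast_1d(np.squeeze(np.asarray(_field(mrk, "pos", "marker structure"), dtype=float))).astype(int)
    if len(labels_raw) != len(positions):
        raise ValueError("marker structure: pos and y lengths differ")
    channel_names = [str(np.squeeze(c)) for c in np.ravel(clab)]
    n_samples = int(round(epoch_s * fs))
    epochs, labels = [], []
    for pos, code in zip(positions, labels_raw):
        if np.isnan(code):
            continue  # unlabeled competition test trial
        if int(code) not in _CLASS_CODES:
            raise ValueError(f"unknown class code {code} in marker structure")
        if pos + n_samples > cnt.shape[0]:
            raise ValueError(f"marker at sample {pos} runs past the end of cnt")
        epochs.append(cnt[pos:pos + n_samples, :].T)
        labels.append(_CLASS_CODES[int(code)])
    if not epochs:
        raise ValueError("no labeled trials found in marker structure")
    return TrialSet(np.stack(epochs), np.array(labels, dtype=object), fs,
                    "sensor", channel_names)


def save_competition_trials(trialset: TrialSet, path: str) -> None:
    """Write a sensor TrialSet in the competition MAT layout (float signal).

    Epochs are concatenated back-to-back into a continuous ``cnt`` block with
    one cue marker at each epoch start, which :func:`load_competition_trials`
    inverts exactly when called with the matching epoch length.
    """
    if trialset.space != "sensor":
        raise ValueError("only sensor-space trial sets can be written in this layout")
    n_trials, n_ch, n_samp = trialset.data.shape
    cnt = trialset.data.transpose(0, 2, 1).reshape(n_trials * n_samp, n_ch)
    pos = np.arange(n_trials) * n_samp
    code = {HAND: 1.0, FOOT: 2.0}
    y = np.array([code[lab] for lab in trialset.labels])
    clab = np.array([np.array([name]) for name in trialset.channel_names], dtype=object)
    spio.savemat(path, {
        "cnt": cnt,
        "mrk": {"pos": pos.astype(float), "y": y},
        "nfo": {"fs": float(trialset.fs), "clab": clab},
    })
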