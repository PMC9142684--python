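"""Containers and file I/O for multi-session calcium-imaging extractions.

A *session extraction* is the output of a source-extraction pipeline run on
one recording session: a matrix ``A`` of spatial footprints (``d`` pixels
per column, one column per neuron) and a matrix ``C`` of fluorescence traces
(one row per neuron, one column per frame).  A *cell register* is the
tracker's output: one row per tracked cell, one column per session, each
entry the neuron index within that session (or missing).

Pixel convention: 0-based, row-major ``(row, col)`` order; footprints are
stored flattened and reshaped through ``fov_shape``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io

MISSING = -1  #: in-memory missing-entry marker in a cell register


class FormatError(ValueError):
    """Raised when a container file lacks required arrays."""


class ConsistencyError(ValueError):
    """Raised when arrays in a container disagree with each other."""


@dataclasses.dataclass
class SessionExtraction:
    """Spatial footprints and fluorescence traces of one session.

    Parameters
    ----------
    footprints : ndarray, shape (d, K)
        Nonnegative pixel intensities, one column per neuron; ``d = H * W``.
    traces : ndarray, shape (K, T)
        Fluorescence signal (dF/F, arbitrary units), one row per neuron.
    fov_shape : (H, W)
        Field-of-view shape in pixels.
    frame_rate : float, optional
        Acquisition rate in Hz.
    session_id : str, optional
    extras : dict
        Optional pass-through arrays from the extraction pipeline (e.g.
        deconvolved spikes, noise estimates); never interpreted here.
    """

    footprints: np.ndarray
    traces: np.ndarray
    fov_shape: tuple[int, int]
    frame_rate: float | None = None
    session_id: str = ""
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        self.fov_shape = (int(self.fov_shape[0]), int(self.fov_shape[1]))
        d, k = self.footprints.shape
        if d != self.fov_shape[0] * self.fov_shape[1]:
            raise ConsistencyError(
                f"footprint length {d} != H*W {self.fov_shape[0] * self.fov_shape[1]}"
            )
        if self.traces.shape[0] != k:
            raise ConsistencyError(
                f"{k} footprints but {self.traces.shape[0]} traces"
            )
        if np.any(self.footprints < 0):
            raise ConsistencyError("footprints must be nonnegative")
        if k and not np.all(self.footprints.max(axis=0) > 0):
            raise ConsistencyError("each footprint needs at least one positive pixel")

    @property
    def n_neurons(self) -> int:
        return self.footprints.shape[1]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def footprint_image(self, i: int) -> np.ndarray:
        """Footprint ``i`` reshaped to the field of view (H, W)."""
        return self.footprints[:, i].reshape(self.fov_shape)


@dataclasses.dataclass
class LinkExtraction:
    """Extraction of a connecting recording spanning a session boundary.

    The connecting recording concatenates the last ``n`` frames of the left
    session with the first ``n`` frames of the right session, so a neuron
    active on both sides ties identities across the boundary.
    """

    extraction: SessionExtraction
    n_frames_each_side: int
    left_session_id: str = ""
    right_session_id: str = ""

    def __post_init__(self) -> None:
        if self.extraction.n_frames != 2 * self.n_frames_each_side:
            raise ConsistencyError(
                "link recording must have exactly 2 * n_frames_each_side frames"
            )

    def first_half(self, i: int) -> np.ndarray:
        return self.extraction.traces[i, : self.n_frames_each_side]

    def second_half(self, i: int) -> np.ndarray:
        return self.extraction.traces[i, self.n_frames_each_side:]


class CellRegister:
    """Table of tracked cells: rows = cells, columns = sessions.

    Entries are 0-based neuron indices within each session, ``MISSING`` (-1)
    where a cell was not found.  ``scores`` holds one aggregate similarity
    per row, in [0, 1].
    """

    def __init__(self, table: pd.DataFrame, scores: Sequence[float] | None = None):
        table = table.astype(int)
        if scores is None:
            scores = np.ones(len(table))
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(table):
            raise ConsistencyError("one score per register row required")
        for col in table.columns:
            vals = table[col].to_numpy()
            vals = vals[vals != MISSING]
            if len(np.unique(vals)) != len(vals):
                raise ConsistencyError(f"duplicate neuron index in session {col!r}")
        if len(table) and not (table.to_numpy() != MISSING).any(axis=1).all():
            raise ConsistencyError("register row with no entries")
        self.table = table.reset_index(drop=True)
        self.scores = scores

    @property
    def sessions(self) -> list:
        return list(self.table.columns)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CellRegister)
            and self.table.equals(other.table)
            and np.allclose(self.scores, other.scores)
        )

    def row_sets(self) -> list[frozenset]:
        """Each row as a set of (session, neuron-index) pairs."""
        out = []
        for _, row in self.table.iterrows():
            out.append(
                frozenset(
                    (s, int(v)) for s, v in row.items() if int(v) != MISSING
                )
            )
        return out


@dataclasses.dataclass
class TrackedSignal:
    """Concatenated trace of one tracked cell across all sessions.

    ``signal`` has length sum(T_s); frames of sessions where the cell was
    missing hold NaN and are flagged in ``missing_mask``.
    """

    signal: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.signal.shape != self.missing_mask.shape:
            raise ConsistencyError("signal and mask shapes differ")


# ---------------------------------------------------------------------------
# session extraction I/O

_DIALECTS = ("hdf5", "mat", "npz")


def write_extraction(extraction: SessionExtraction, path, dialect: str = "hdf5") -> None:
    """Write a session extraction to ``path`` (datasets A, C, fov)."""
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("A", data=extraction.footprints)
            f.create_dataset("C", data=extraction.traces)
            f.create_dataset("fov", data=np.asarray(extraction.fov_shape))
            if extraction.frame_rate is not None:
                f.attrs["frame_rate"] = extraction.frame_rate
            f.attrs["session_id"] = extraction.session_id
    elif dialect == "mat":
        mdict = {
            "A": extraction.footprints,
            "C": extraction.traces,
            "fov": np.asarray(extraction.fov_shape),
        }
        if extraction.frame_rate is not None:
            mdict["frame_rate"] = extraction.frame_rate
        scipy.io.savemat(path, mdict)
    elif dialect == "npz":
        np.savez(
            path,
            A=extraction.footprints,
            C=extraction.traces,
            fov=np.asarray(extraction.fov_shape),
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")


def read_extraction(path, dialect: str = "hdf5") -> SessionExtraction:
    """Read a session extraction written by :func:`write_extraction`.

    Raises
    ------
    FormatError
        If the A/C/fov arrays are absent.
    ConsistencyError
        If the neuron counts of A and C disagree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame_rate = None
    session_id = ""
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("A", "C", "fov"):
                if key not in f:
                    raise FormatError(f"dataset {key!r} missing from {path}")
            a = f["A"][()]
            c = f["C"][()]
            fov = tuple(int(v) for v in f["fov"][()])
            frame_rate = f.attrs.get("frame_rate")
            session_id = str(f.attrs.get("session_id", ""))
    elif dialect == "mat":
        mdict = scipy.io.loadmat(path)
        for key in ("A", "C", "fov"):
            if key not in mdict:
                raise FormatError(f"array {key!r} missing from {path}")
        a = mdict["A"]
        c = np.atleast_2d(mdict["C"])
        fov = tuple(int(v) for v in np.ravel(mdict["fov"]))
        if "frame_rate" in mdict:
            frame_rate = float(np.ravel(mdict["frame_rate"])[0])
    elif dialect == "npz":
        with np.load(path) as npz:
            for key in ("A", "C", "fov"):
                if key not in npz:
                    raise FormatError(f"array {key!r} missing from {path}")
            a = npz["A"]
            c = npz["C"]
            fov = tuple(int(v) for v in npz["fov"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    return SessionExtraction(
        footprints=a,
        traces=c,
        fov_shape=fov,
        frame_rate=None if frame_rate is None else float(frame_rate),
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# cell register I/O
#
# CSV dialect uses 1-based indices with 0 as the missing marker (the common
# MATLAB-style register layout); scores travel in a trailing column.

_SCORE_COL = "score"


def write_register(register: CellRegister, path) -> None:
    path = Path(path)
    out = register.table + 1  # 1-based on disk, 0 = missing
    out[out == MISSING + 1] = 0
    out[_SCORE_COL] = register.scores
    out.to_csv(path, index=False)


def read_register(path) -> CellRegister:
    path = Path(path)
    df = pd.read_csv(path)
    if _SCORE_COL in df.columns:
        scores = df.pop(_SCORE_COL).to_numpy()
    else:
        scores = None
    table = df.astype(int) - 1  # 0 on disk -> MISSING (-1)
    return CellRegister(table, scores)


# ---------------------------------------------------------------------------


def concatenate_traces(
    register: CellRegister, sessions: Sequence[SessionExtraction]
) -> list[TrackedSignal]:
    """Concatenate each tracked cell's traces across sessions.

    Sessions missing a cell contribute NaN-filled, masked frames, so every
    returned signal has length ``sum(T_s)``.
    """
    if len(sessions) != len(register.sessions):
        raise ConsistencyError(
            f"register has {len(register.sessions)} sessions, got {len(sessions)}"
        )
    lengths = [s.n_frames for s in sessions]
    total = int(np.sum(lengths))
    starts = np.concatenate([[0], np.cumsum(lengths)])
    out = []
    for _, row in register.table.iterrows():
        signal = np.full(total, np.nan)
        mask = np.ones(total, dtype=bool)
        for j, (sess, idx) in enumerate(zip(sessions, row.to_numpy())):
            idx = int(idx)
            if idx == MISSING:
                continue
            if idx < 0 or idx >= sess.n_neurons:
                raise IndexError(
                    f"register references neuron {idx} of session {j} "
                    f"(K={sess.n_neurons})"
                )
            signal[starts[j]: starts[j + 1]] = sess.traces[idx]
            mask[starts[j]: starts[j + 1]] = False
        out.append(TrackedSignal(signal=signal, missing_mask=mask))
    return out
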