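"""Signature containers, label vocabulary, HDF5 I/O and split utilities.

A *signature* is the (channels x time) matrix extracted around one
naturally evoked compound action potential, labeled with the afferent
activity that evoked it (dorsiflexion, plantarflexion or pricking) and the
subject the recording came from.  All pipeline stages consume one schema so
real and synthetic data are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .geometry import CuffLayout

__all__ = [
    "LABELS",
    "Signature",
    "SignatureDataset",
    "SchemaError",
    "StratificationError",
    "save_dataset",
    "load_dataset",
    "split_by_subject",
    "split_within_subject",
]

LABELS = ("dorsiflexion", "plantarflexion", "pricking")
LABEL_TO_CODE = {name: i for i, name in enumerate(LABELS)}


class SchemaError(ValueError):
    """A record violates the dataset schema."""


class StratificationError(ValueError):
    """Too few samples of some class to build stratified folds."""


@dataclass
class Signature:
    """One (channels x time) matrix with its class label and subject id."""

    values: np.ndarray
    label: str
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise SchemaError("signature values must be a 2-D matrix")
        if self.label not in LABELS:
            raise SchemaError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("signature contains non-finite values")

    @property
    def label_code(self) -> int:
        return LABEL_TO_CODE[self.label]


@dataclass
class SignatureDataset:
    """An ordered collection of signatures over one cuff layout."""

    signatures: list[Signature]
    layout: CuffLayout = field(default_factory=CuffLayout)

    def __post_init__(self):
        n = self.layout.n_nodes
        shapes = {s.values.shape for s in self.signatures}
        if len(shapes) > 1:
            raise SchemaError(f"signatures have mixed shapes: {sorted(shapes)}")
        for pos, s in enumerate(self.signatures):
            if s.values.shape[0] != n:
                raise SchemaError(
                    f"signature {pos} (subject {s.subject_id!r}) has "
                    f"{s.values.shape[0]} rows, layout has {n} nodes")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def values(self) -> np.ndarray:
        """Stacked (N, channels, time) array."""
        return np.stack([s.values for s in self.signatures])

    @property
    def labels(self) -> np.ndarray:
        """Integer label codes, shape (N,)."""
        return np.array([s.label_code for s in self.signatures], dtype=np.int64)

    @property
    def subjects(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.signatures])

    @property
    def subject_ids(self) -> list[str]:
        """Distinct subject ids in sorted order."""
        return sorted(set(s.subject_id for s in self.signatures))

    def subset(self, indices) -> "SignatureDataset":
        return SignatureDataset([self.signatures[int(i)] for i in indices], self.layout)


def save_dataset(ds: SignatureDataset, path) -> None:
    """Write the HDF5 schema: /signatures (N x C x T float32), /labels
    (integer codes), /subjects (UTF-8), plus layout attributes."""
    values = ds.values.astype(np.float32)
    # track_times=False keeps the file bytes deterministic for a given dataset
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signatures", data=values, track_times=False)
        fh.create_dataset("labels", data=ds.labels, track_times=False)
        fh.create_dataset("subjects", data=ds.subjects.astype(object),
                          dtype=h5py.string_dtype("utf-8"), track_times=False)
        fh.attrs["n_rings"] = ds.layout.n_rings
        fh.attrs["n_contacts"] = ds.layout.n_contacts
        fh.attrs["n_timesamples"] = values.shape[2] if len(ds) else 0


def load_dataset(path) -> SignatureDataset:
    """Read and validate a dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as fh:
        for name in ("signatures", "labels", "subjects"):
            if name not in fh:
                raise SchemaError(f"missing dataset /{name} in {path}")
        values = fh["signatures"][()]
        codes = fh["labels"][()]
        subjects = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in fh["subjects"][()]]
        layout = CuffLayout(int(fh.attrs["n_rings"]), int(fh.attrs["n_contacts"]))
    if values.ndim != 3:
        raise SchemaError("/signatures must be a 3-D array (N x channels x time)")
    if not (len(values) == len(codes) == len(subjects)):
        raise SchemaError("mismatched record counts across /signatures, /labels, /subjects")
    sigs = []
    for pos, (mat, code, subj) in enumerate(zip(values, codes, subjects)):
        if not 0 <= code < len(LABELS):
            raise SchemaError(f"record {pos}: unknown label code {code}")
        if not subj:
            raise SchemaError(f"record {pos}: missing subject id")
        sigs.append(Signature(values=mat, label=LABELS[int(code)], subject_id=subj))
    return SignatureDataset(sigs, layout)


def split_by_subject(ds: SignatureDataset, held_out: str
                     ) -> tuple[SignatureDataset, SignatureDataset]:
    """Leave-one-subject-out split: test = the held-out subject, train = rest."""
    if held_out not in ds.subject_ids:
        raise ValueError(f"unknown subject {held_out!r}; have {ds.subject_ids}")
    subjects = ds.subjects
    test_idx = np.flatnonzero(subjects == held_out)
    train_idx = np.flatnonzero(subjects != held_out)
    return ds.subset(train_idx), ds.subset(test_idx)


def split_within_subject(ds: SignatureDataset, subject: str, n_folds: int,
                         fold: int, seed: int
                         ) -> tuple[SignatureDataset, SignatureDataset]:
    """One subject's signatures partitioned into label-stratified folds.

    Returns (train, test) where test is fold ``fold`` and train is the
    union of the remaining folds; deterministic under ``seed``.
    """
    if subject not in ds.subject_ids:
        raise ValueError(f"unknown subject {subject!r}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must be in [0, {n_folds}), got {fold}")
    idx = np.flatnonzero(ds.subjects == subject)
    labels = ds.labels[idx]
    counts = np.bincount(labels, minlength=len(LABELS))
    short = [LABELS[c] for c in range(len(LABELS)) if 0 < counts[c] < n_folds]
    if short:
        raise StratificationError(
            f"subject {subject!r} has fewer than {n_folds} signatures of "
            f"class(es) {short}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    train_pos, test_pos = list(skf.split(idx, labels))[fold]
    return ds.subset(idx[train_pos]), ds.subset(idx[test_pos])
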