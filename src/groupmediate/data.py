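"""Core data containers: the observed dataset and the group coding.

A :class:`MediationDataset` holds per-observation values of the independent
variable X, the mediator M, the outcome Y, and a two-level group label. It is
the universal input to every fitting, inference, and resampling routine in
this package. Group labels are normalised to strings; all results are reported
per label, never per numeric code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["GroupCoding", "MediationDataset"]


@dataclass(frozen=True)
class GroupCoding:
    """Dummy coding of the two-level moderator.

    The reference group is coded 0 and the focal group 1 in the single-group
    interaction model, so ``a1`` is the X->M slope in the reference group and
    ``a3`` the focal-minus-reference difference in that slope. Which label
    plays which role is an explicit user choice: the substantive estimands
    (per-group simple indirect effects) do not depend on it, only the sign of
    the difference does.
    """

    reference: str
    focal: str

    def __post_init__(self):
        if self.reference == self.focal:
            raise DataError("reference and focal labels must be distinct")

    def swapped(self) -> "GroupCoding":
        return GroupCoding(reference=self.focal, focal=self.reference)


@dataclass
class MediationDataset:
    """Rectangular X/M/Y data with a two-level group label.

    Vectors must have equal length, contain no missing values (rows with
    missing cells are rejected at load time, see :func:`groupmediate.io.
    load_dataset`), and exactly two distinct group labels must be present.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    group: np.ndarray
    n_dropped: int = 0  # rows rejected at load time (listwise)
    labels: tuple[str, str] = field(init=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.group = np.asarray([str(g) for g in np.asarray(self.group).ravel()], dtype=object)
        n = len(self.x)
        if not (len(self.m) == len(self.y) == len(self.group) == n) or n < 1:
            raise DataError("x, m, y, group must have equal length >= 1")
        for name, v in (("x", self.x), ("m", self.m), ("y", self.y)):
            if not np.all(np.isfinite(v)):
                raise DataError(f"column {name!r} contains missing or non-finite values")
        labels = tuple(sorted(set(self.group)))
        if len(labels) != 2:
            raise DataError(
                f"exactly two group labels are required, found {len(labels)}: {labels}"
            )
        self.labels = labels  # sorted, deterministic

    @property
    def n_total(self) -> int:
        return len(self.x)

    @property
    def n_per_group(self) -> dict[str, int]:
        return {lab: int(np.sum(self.group == lab)) for lab in self.labels}

    def mask(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise DataError(f"unknown group label {label!r}; have {self.labels}")
        return self.group == label

    def arrays(self, label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, m, y) restricted to one group."""
        k = self.mask(label)
        return self.x[k], self.m[k], self.y[k]

    def default_coding(self) -> GroupCoding:
        """First label (sorted order) as reference, second as focal."""
        return GroupCoding(reference=self.labels[0], focal=self.labels[1])

    def fingerprint(self) -> str:
        """Stable digest of the data; used to check that nested fits share data."""
        h = hashlib.sha1()
        h.update(self.x.tobytes())
        h.update(self.m.tobytes())
        h.update(self.y.tobytes())
        h.update("\x00".join(self.group).encode())
        return h.hexdigest()
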