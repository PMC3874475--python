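"""Electrode montages.

A montage names every recorded channel, assigns it a role (scalp EEG,
mastoid reference lead, or EOG) and places it on a unit sphere modelling
the head.  Positions are only consumed by the spherical-spline machinery
(bad-channel repair, surface Laplacian) and by the simulator's component
topographies, so a geometrically plausible idealized layout is sufficient;
no digitized coordinates are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_standard_montage", "FRONTOCENTRAL_9"]

#: The nine fronto-central electrodes over which the mismatch negativity is
#: classically maximal and over which grand-average difference waves are
#: usually summarized.
FRONTOCENTRAL_9 = ("F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2")


@dataclass(frozen=True)
class Montage:
    """Channel labels, unit-sphere positions and per-channel roles.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 3)
        Cartesian coordinates on the unit sphere (head-centred; +x right,
        +y anterior, +z superior).
    roles : tuple of str
        One of ``{"eeg", "mastoid", "eog"}`` per channel.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    roles: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        roles = tuple(self.roles)
        pos = np.asarray(self.positions, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("all montage positions must have unit norm")
        bad_roles = set(roles) - {"eeg", "mastoid", "eog"}
        if bad_roles:
            raise ValueError(f"unknown channel roles: {sorted(bad_roles)}")
        if len(roles) != len(labels):
            raise ValueError("roles length must match labels")
        if roles.count("eeg") < 1:
            raise ValueError("montage needs at least one eeg channel")
        if roles.count("mastoid") not in (0, 2):
            raise ValueError("mastoid role must appear exactly 0 or 2 times")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def indices(self, labels) -> np.ndarray:
        return np.array([self._index[l] for l in labels], dtype=int)

    def role_indices(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.roles) if r == role], dtype=int
        )

    @property
    def eeg_indices(self) -> np.ndarray:
        return self.role_indices("eeg")

    def subset(self, indices) -> "Montage":
        idx = np.asarray(indices, dtype=int)
        return Montage(
            tuple(self.labels[i] for i in idx),
            self.positions[idx],
            tuple(self.roles[i] for i in idx),
        )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "positions": self.positions.tolist(),
            "roles": list(self.roles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(tuple(d["labels"]), np.asarray(d["positions"]), tuple(d["roles"]))


#: Lateral angles for the nine-column rows (7 ... z ... 8), degrees.
_COLS9 = {
    "7": -72, "5": -54, "3": -36, "1": -18, "z": 0,
    "2": 18, "4": 36, "6": 54, "8": 72,
}


def _place(ap_deg: float, lat_deg: float) -> np.ndarray:
    """Unit-sphere position from two head angles.

    ``ap_deg`` tilts the vertex vector toward the nasion (+) or inion (−);
    ``lat_deg`` then tilts toward the right (+) or left (−) ear.  The
    central coronal row (ap=0) stays exactly in the y=0 plane.
    """
    ap = np.deg2rad(ap_deg)
    lat = np.deg2rad(lat_deg)
    v = np.array(
        [np.cos(ap) * np.sin(lat), np.sin(ap), np.cos(ap) * np.cos(lat)]
    )
    return v / np.linalg.norm(v)


def make_standard_montage() -> Montage:
    """Synthetic idealized 64-channel scalp montage + 2 mastoids + 2 EOG.

    The layout is a 10-10-style arrangement generated from row/column angle
    specifications; it is *synthetic* — plausible geometry with standard
    labels, not digitized coordinates.  It covers the labels needed to
    address the fronto-central mismatch cluster (``FRONTOCENTRAL_9``).
    """
    # Anterior-posterior angle per row prefix; lateral angle per column.
    rows = [
        ("Fp", 72, {"1": -18, "z": 0, "2": 18}),
        ("AF", 54, {"7": -54, "3": -27, "z": 0, "4": 27, "8": 54}),
        ("F", 36, _COLS9),
        ("FC", 18, dict(_COLS9, **{"7": None, "8": None})),  # FT7/8 below
        ("C", 0, _COLS9),
        ("CP", -18, dict(_COLS9, **{"7": None, "8": None})),  # TP7/8 below
        ("P", -36, dict(_COLS9, **{"9": -90, "10": 90})),
        ("PO", -54, {"7": -54, "3": -27, "z": 0, "4": 27, "8": 54}),
        ("O", -72, {"1": -18, "z": 0, "2": 18}),
    ]
    labels: list[str] = []
    positions: list[np.ndarray] = []

    def add(label: str, ap: float, lat: float) -> None:
        labels.append(label)
        positions.append(_place(ap, lat))

    for prefix, ap, cols in rows:
        for col, lat in cols.items():
            if lat is None:
                continue
            name = f"{prefix}{col}"
            # The lateral-most mid rows carry T/FT/TP names in the 10-10 system.
            name = {"C7": "T7", "C8": "T8"}.get(name, name)
            add(name, ap, lat)
    add("FT7", 18, -81)
    add("FT8", 18, 81)
    add("TP7", -18, -81)
    add("TP8", -18, 81)
    add("Iz", -90, 0)
    roles = ["eeg"] * len(labels)
    # Mastoid leads behind/below the ears, and two EOG channels near the eyes.
    extra = [
        ("M1", np.array([-0.98, -0.15, -0.13]), "mastoid"),
        ("M2", np.array([0.98, -0.15, -0.13]), "mastoid"),
        ("EOGh", np.array([-0.80, 0.58, -0.16]), "eog"),
        ("EOGv", np.array([0.31, 0.93, -0.19]), "eog"),
    ]
    for label, pos, role in extra:
        labels.append(label)
        positions.append(pos / np.linalg.norm(pos))
        roles.append(role)
    assert len(labels) == 68 and roles.count("eeg") == 64
    return Montage(tuple(labels), np.array(positions), tuple(roles))
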