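"""Labelled SERS spectrum collections and their on-disk format.

The atomic object of the pipeline is a set of Raman spectra sharing one
shift grid, each carrying an AMP:ADP:ATP mixing-ratio label.  Seven ratio
patterns are studied (1:0:0, 0:1:0, 0:0:1, 1:1:0, 1:0:1, 0:1:1, 1:1:1);
each pattern defines a *group* and, through its non-zero entries, a
presence/absence triplet for the three adenosine phosphates.

On disk a set is a wide CSV (first column ``raman_shift_cm-1``, one column
per spectrum) plus a JSON sidecar holding per-spectrum labels and, when the
set was simulated, the generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPECIES: tuple[str, str, str] = ("AMP", "ADP", "ATP")

#: Canonical ordering of the seven volume-ratio groups; group ids are 1-based.
GROUP_RATIOS: dict[int, tuple[int, int, int]] = {
    1: (1, 0, 0),
    2: (0, 1, 0),
    3: (0, 0, 1),
    4: (1, 1, 0),
    5: (1, 0, 1),
    6: (0, 1, 1),
    7: (1, 1, 1),
}

#: Presence triplet (AMP, ADP, ATP) implied by each group id.
PRESENCE_BY_GROUP: dict[int, tuple[bool, bool, bool]] = {
    g: tuple(r > 0 for r in ratio) for g, ratio in GROUP_RATIOS.items()
}

_PATTERN_TO_GROUP = {
    tuple(r > 0 for r in ratio): g for g, ratio in GROUP_RATIOS.items()
}

LABEL_COLUMNS = (
    "spectrum_id",
    "group_id",
    "ratio_amp",
    "ratio_adp",
    "ratio_atp",
    "has_amp",
    "has_adp",
    "has_atp",
    "origin",
    "source_id",
)


def presence_from_ratio(ratio: Sequence[float]) -> tuple[bool, bool, bool]:
    """Presence triplet of a mixing ratio: component present iff its entry > 0."""
    if len(ratio) != 3:
        raise ValueError(f"ratio must have 3 entries, got {len(ratio)}")
    if any(r < 0 for r in ratio):
        raise ValueError(f"ratio entries must be non-negative, got {tuple(ratio)}")
    if not any(r > 0 for r in ratio):
        raise ValueError("all-zero mixing ratio has no presence pattern")
    return tuple(r > 0 for r in ratio)  # type: ignore[return-value]


def group_from_ratio(ratio: Sequence[float]) -> int:
    """Group id (1-7) determined by the non-zero pattern of a mixing ratio."""
    pattern = presence_from_ratio(ratio)
    return _PATTERN_TO_GROUP[pattern]


def _label_frame(records: Iterable[dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(records))
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label records missing columns: {sorted(missing)}")
    return df.loc[:, list(LABEL_COLUMNS)].reset_index(drop=True)


def make_labels(
    spectrum_ids: Sequence[str],
    ratios: Sequence[Sequence[float]],
    origin: str = "measured",
    source_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a label table from ids and mixing ratios.

    Group ids and presence triplets are derived from the ratios, enforcing
    the presence[c] <-> ratio[c] > 0 invariant by construction.
    """
    if len(spectrum_ids) != len(ratios):
        raise ValueError("spectrum_ids and ratios must have equal length")
    if source_ids is None:
        source_ids = ["" for _ in spectrum_ids]
    records = []
    for sid, ratio, src in zip(spectrum_ids, ratios, source_ids):
        presence = presence_from_ratio(ratio)
        records.append(
            {
                "spectrum_id": str(sid),
                "group_id": group_from_ratio(ratio),
                "ratio_amp": float(ratio[0]),
                "ratio_adp": float(ratio[1]),
                "ratio_atp": float(ratio[2]),
                "has_amp": bool(presence[0]),
                "has_adp": bool(presence[1]),
                "has_atp": bool(presence[2]),
                "origin": origin,
                "source_id": str(src),
            }
        )
    return _label_frame(records)


@dataclasses.dataclass
class SpectrumSet:
    """A collection of spectra on one shared, strictly increasing shift grid.

    Parameters
    ----------
    shifts
        Raman shift grid in cm^-1, shape ``(m,)``, strictly increasing.
    intensities
        Intensity matrix, shape ``(n_spectra, m)``, arbitrary units.
    labels
        One row per spectrum with the columns of :data:`LABEL_COLUMNS`.
    meta
        Free-form provenance (e.g. the generating config), serialized with
        the sidecar.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    labels: pd.DataFrame
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.shifts.ndim != 1:
            raise ValueError("shifts must be one-dimensional")
        if self.intensities.shape[1] != self.shifts.shape[0]:
            raise ValueError(
                f"intensity columns ({self.intensities.shape[1]}) must match "
                f"grid length ({self.shifts.shape[0]})"
            )
        if self.shifts.size >= 2 and not np.all(np.diff(self.shifts) > 0):
            raise ValueError("shifts must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if len(self.labels) != self.intensities.shape[0]:
            raise ValueError(
                f"label rows ({len(self.labels)}) must match spectrum count "
                f"({self.intensities.shape[0]})"
            )
        self.labels = self.labels.reset_index(drop=True)
        ratios = self.labels[["ratio_amp", "ratio_adp", "ratio_atp"]].to_numpy()
        presence = self.labels[["has_amp", "has_adp", "has_atp"]].to_numpy(bool)
        if not np.array_equal(presence, ratios > 0):
            bad = np.nonzero((presence != (ratios > 0)).any(axis=1))[0]
            raise ValueError(
                f"presence/ratio mismatch for spectra {list(self.labels.spectrum_id.iloc[bad])}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_shifts(self) -> int:
        return self.shifts.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Group-id vector (1-7), the classification target."""
        return self.labels["group_id"].to_numpy(int)

    @property
    def presence(self) -> np.ndarray:
        """Boolean (n, 3) presence matrix in AMP, ADP, ATP order."""
        return self.labels[["has_amp", "has_adp", "has_atp"]].to_numpy(bool)

    def subset(self, rows: Sequence[int]) -> "SpectrumSet":
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(
            shifts=self.shifts.copy(),
            intensities=self.intensities[rows].copy(),
            labels=self.labels.iloc[rows].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def select_shifts(self, indices: Sequence[int]) -> "SpectrumSet":
        """Restrict every spectrum to the given shift indices (ascending)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot select an empty shift set")
        return SpectrumSet(
            shifts=self.shifts[idx].copy(),
            intensities=self.intensities[:, idx].copy(),
            labels=self.labels.copy(),
            meta=dict(self.meta),
        )

    def with_intensities(self, intensities: np.ndarray, shifts: np.ndarray | None = None) -> "SpectrumSet":
        return SpectrumSet(
            shifts=self.shifts.copy() if shifts is None else np.asarray(shifts, float),
            intensities=intensities,
            labels=self.labels.copy(),
            meta=dict(self.meta),
        )

    @staticmethod
    def concat(sets: Sequence["SpectrumSet"]) -> "SpectrumSet":
        if not sets:
            raise ValueError("cannot concatenate zero sets")
        first = sets[0]
        for s in sets[1:]:
            if not np.array_equal(s.shifts, first.shifts):
                raise ValueError("cannot concatenate sets on different grids")
        return SpectrumSet(
            shifts=first.shifts.copy(),
            intensities=np.vstack([s.intensities for s in sets]),
            labels=pd.concat([s.labels for s in sets], ignore_index=True),
            meta=dict(first.meta),
        )

    # -- persistence ------------------------------------------------------

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` (wide) and ``<prefix>.labels.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.parent / (prefix.name + ".labels.json")
        wide = pd.DataFrame({"raman_shift_cm-1": self.shifts})
        for i, sid in enumerate(self.labels["spectrum_id"]):
            wide[sid] = self.intensities[i]
        wide.to_csv(csv_path, index=False)
        sidecar = {
            "meta": self.meta,
            "spectra": self.labels.to_dict(orient="records"),
        }
        json_path.write_text(json.dumps(sidecar, indent=1))
        return csv_path, json_path

    @classmethod
    def from_files(cls, prefix: str | Path) -> "SpectrumSet":
        prefix = Path(prefix)
        wide = pd.read_csv(prefix.with_suffix(".csv"))
        sidecar = json.loads((prefix.parent / (prefix.name + ".labels.json")).read_text())
        labels = _label_frame(sidecar["spectra"])
        ids = list(labels["spectrum_id"])
        return cls(
            shifts=wide["raman_shift_cm-1"].to_numpy(float),
            intensities=wide.loc[:, ids].to_numpy(float).T,
            labels=labels,
            meta=sidecar.get("meta", {}),
        )
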