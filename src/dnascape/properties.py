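"""Dinucleotide structural-property models and property tracks.

A property model assigns one value to each of the 16 dinucleotide steps
(Roll, Twist, Slide, stiffness constants, persistence length, ...).  Applied
to a binned dinucleotide map it yields a structural-property track: per bin
either the sum of ``m_XY * n_XY`` over all dinucleotides, or that sum divided
by the total dinucleotide count (the mean per step, the default — it keeps
bins with different valid lengths comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import DINUCLEOTIDES
from .maps import DinucleotideTrackSet
from .tracks import BinnedTrack


@dataclass
class PropertyModel:
    """Named 16-value dinucleotide model (AA..TT order)."""

    id: int
    name: str
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (16,):
            raise ValueError("a property model needs exactly 16 dinucleotide values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("model values must be finite")

    def __getitem__(self, xy: str) -> float:
        return float(self.values[DINUCLEOTIDES.index(xy.upper())])

    @property
    def label(self) -> str:
        return f"{self.name}({self.id})"


@dataclass
class PropertyTrack:
    """A BinnedTrack of property values plus its provenance."""

    track: BinnedTrack
    model_id: int
    model_name: str
    mode: str

    @property
    def values(self) -> np.ndarray:
        return self.track.values


class ModelTable:
    """Collection of property models keyed by id and by name."""

    def __init__(self, models: list[PropertyModel]):
        self.models = models
        self.by_id = {m.id: m for m in models}
        self.by_name: dict[str, list[PropertyModel]] = {}
        for m in models:
            self.by_name.setdefault(m.name, []).append(m)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def get(self, key: int | str) -> PropertyModel:
        """Look up by id, by ``Name(id)`` label, or by unique name."""
        if isinstance(key, int):
            return self.by_id[key]
        key = key.strip()
        if key.endswith(")") and "(" in key:
            name, _, idpart = key.rpartition("(")
            return self.by_id[int(idpart[:-1])]
        matches = self.by_name.get(key, [])
        if len(matches) != 1:
            raise KeyError(f"model name {key!r} matches {len(matches)} models; use an id")
        return matches[0]


def load_model_table(path: str | Path) -> ModelTable:
    """Load a TSV of property models (columns: id, name, AA, AC, ..., TT)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("id", "name", *DINUCLEOTIDES) if c not in df.columns]
    if missing:
        raise ValueError(f"model table is missing columns: {missing}")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
        raise ValueError(f"duplicate model ids: {dups}")
    values = df[list(DINUCLEOTIDES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("model table contains missing or non-finite values")
    extra = [c for c in df.columns if c not in ("id", "name", *DINUCLEOTIDES)]
    models = [
        PropertyModel(int(row["id"]), str(row["name"]), values[i],
                      {c: row[c] for c in extra})
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return ModelTable(models)


def bundled_models() -> ModelTable:
    """The model table shipped with the package (a small synthetic fixture of
    named models with literature-typical magnitudes, not the full database)."""
    with resources.as_file(
        resources.files("dnascape").joinpath("data/dinucleotide_properties.tsv")
    ) as p:
        return load_model_table(p)


def apply_model(model: PropertyModel, dinucs: DinucleotideTrackSet,
                mode: str = "mean") -> PropertyTrack:
    """Turn a dinucleotide map into a property track.

    ``sum`` mode: per bin ``sum_XY m_XY * n_XY``.  ``mean`` mode divides by the
    bin's total dinucleotide count.  Invalid bins (low valid fraction, or an
    empty bin under ``mean``) propagate as NaN, never as a division error.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    counts = dinucs.dinuc_counts.astype(float)
    vals = counts @ model.values
    if mode == "mean":
        total = dinucs.total_dinucs.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(total > 0, vals / np.where(total > 0, total, 1), np.nan)
    vals = np.where(dinucs.valid, vals, np.nan)
    track = BinnedTrack(dinucs.chrom, dinucs.resolution, vals, dinucs.valid_fraction)
    return PropertyTrack(track, model.id, model.name, mode)
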