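"""Tabular I/O: feature tables, sample metadata, adduct rules.

Feature tables are accepted in two dialects, auto-detected from the header:

* long — columns ``feature_id, mz, rt, polarity, sample_id, area``
* wide — a feature-metadata block (``feature_id, mz, rt, polarity``)
  followed by one column per sample

Both parse to the same :class:`FeatureTable`.  Delimiter is inferred from
the file extension (``.csv`` → comma, otherwise tab).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import AdductRule, DEFAULT_ADDUCT_RULES

FEATURE_COLUMNS = ("feature_id", "mz", "rt", "polarity")
LONG_COLUMNS = FEATURE_COLUMNS + ("sample_id", "area")
META_COLUMNS = (
    "sample_id",
    "role",
    "isolate_id",
    "medium_id",
    "control_group_id",
    "timepoint_min",
    "replicate",
)
ROLES = ("control", "spent", "cell_extract", "soil_water")
POLARITIES = ("positive", "negative")


@dataclass
class FeatureTable:
    """Spectral features x samples.

    ``features``: DataFrame indexed by feature_id with columns mz, rt,
    polarity.  ``intensities``: DataFrame (feature_id x sample_id) of peak
    areas; 0 means not detected.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = self.features.loc[:, ["mz", "rt", "polarity"]]
        self.features.index.name = "feature_id"
        if not self.features.index.equals(self.intensities.index):
            self.intensities = self.intensities.reindex(self.features.index)
        self.intensities.index.name = "feature_id"
        self.intensities.columns.name = "sample_id"
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def validate(self) -> None:
        f, x = self.features, self.intensities
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if x.isna().any().any():
            raise ValueError("missing intensity entries (every feature needs a value per sample)")
        arr = x.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("non-finite intensities")
        if (arr < 0).any():
            raise ValueError("negative peak areas")
        if (f["mz"] <= 0).any():
            raise ValueError("m/z must be positive")
        if (f["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")
        bad = set(f["polarity"]) - set(POLARITIES)
        if bad:
            raise ValueError(f"unknown polarity values: {sorted(bad)}")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a long- or wide-format feature table (dialect auto-detected)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "sample_id" in df.columns and "area" in df.columns:
        dup = df.duplicated(subset=["feature_id", "sample_id"])
        if dup.any():
            rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
            raise ValueError(f"{path}: duplicate (feature_id, sample_id) at line(s) {rows[:5]}")
        feats = (
            df[list(FEATURE_COLUMNS)]
            .drop_duplicates("feature_id")
            .set_index("feature_id")
            .astype({"mz": float, "rt": float})
        )
        wide = df.pivot(index="feature_id", columns="sample_id", values="area")
        if wide.isna().any().any():
            raise ValueError(f"{path}: long table is ragged — not every feature has every sample")
        return FeatureTable(feats, wide.reindex(feats.index).astype(float))
    sample_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    feats = df[list(FEATURE_COLUMNS)].set_index("feature_id").astype({"mz": float, "rt": float})
    inten = df.set_index("feature_id")[sample_cols].astype(float)
    return FeatureTable(feats, inten)


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "long") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if dialect == "long":
        long = (
            table.intensities.rename_axis(index="feature_id", columns="sample_id")
            .stack()
            .rename("area")
            .reset_index()
        )
        out = long.merge(table.features.reset_index(), on="feature_id")[list(LONG_COLUMNS)]
    elif dialect == "wide":
        out = table.features.join(table.intensities).reset_index()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep=sep, index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep)
    return validate_sample_metadata(meta)


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "role") if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing column(s) {missing}")
    meta = meta.copy()
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = pd.NA
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = set(meta["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown sample roles: {sorted(bad)}")
    spent = meta[meta["role"] == "spent"]
    ctl = meta[meta["role"] == "control"]
    for cg, grp in spent.groupby("control_group_id", dropna=False):
        if pd.isna(cg):
            raise ValueError("spent samples without control_group_id")
        matched = ctl[ctl["control_group_id"] == cg]
        if len(matched) < 2:
            raise ValueError(
                f"control group {cg!r} has {len(matched)} control sample(s); >=2 required"
            )
        media = set(grp["medium_id"]) | set(matched["medium_id"])
        if len(media) > 1:
            raise ValueError(f"control group {cg!r} mixes media {sorted(map(str, media))}")
    return meta.set_index("sample_id") if meta.index.name != "sample_id" else meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta.reset_index().to_csv(path, sep=sep, index=False)


def read_adduct_rules(path: str | Path) -> tuple[AdductRule, ...]:
    """Load an editable YAML adduct-rule list (priority = file order)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        rules.append(
            AdductRule(
                name=entry["name"],
                polarity=entry["polarity"],
                multiplicity=int(entry.get("multiplicity", 1)),
                mass_shift=float(entry["mass_shift"]),
                charge=int(entry.get("charge", 1)),
                characteristic=bool(entry.get("characteristic", False)),
            )
        )
    return tuple(rules)


def write_adduct_rules(rules: tuple[AdductRule, ...], path: str | Path) -> None:
    payload = [
        {
            "name": r.name,
            "polarity": r.polarity,
            "multiplicity": r.multiplicity,
            "mass_shift": r.mass_shift,
            "charge": r.charge,
            "characteristic": r.characteristic,
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def default_adduct_rules() -> tuple[AdductRule, ...]:
    return DEFAULT_ADDUCT_RULES
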