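"""Reaction feature tables, CSV I/O, and enantioselectivity utilities.

A reaction is described by numeric descriptors of the four molecules taking
part in it — solvent, catalyst, nucleophile and imine — plus an optional
enantioselectivity target ΔΔG‡ (kcal/mol).  ΔΔG‡ = −RT·ln(e.r.) where e.r.
is the enantiomeric ratio, T the reaction temperature and R the gas
constant.  This module holds the table data model that every other module
consumes, reads/writes the CSV pair (data + feature-role metadata), and
screens the target distribution for normality and outliers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Reserved CSV column names (never feature names).
ID_COLUMN = "reaction_id"
TARGET_COLUMN = "ddg"

#: |z| threshold used to flag target outliers.
OUTLIER_Z = 3.0


class SchemaError(ValueError):
    """A column/feature is missing or misdescribed."""


class DataError(ValueError):
    """Values violate the data contract (non-finite, degenerate, wrong size)."""


class MoleculeRole(str, enum.Enum):
    """Which molecule of the reaction a descriptor belongs to."""

    SOLVENT = "solvent"
    CATALYST = "catalyst"
    NUCLEOPHILE = "nucleophile"
    IMINE = "imine"


class FeatureView(str, enum.Enum):
    """Feature subset used for training.

    ``EXCLUDE_IMINE`` corresponds to nucleophile-focused models,
    ``EXCLUDE_NUCLEOPHILE`` to imine-focused models.
    """

    ALL = "all"
    EXCLUDE_IMINE = "exclude_imine"
    EXCLUDE_NUCLEOPHILE = "exclude_nucleophile"

    @property
    def dropped_role(self) -> MoleculeRole | None:
        if self is FeatureView.EXCLUDE_IMINE:
            return MoleculeRole.IMINE
        if self is FeatureView.EXCLUDE_NUCLEOPHILE:
            return MoleculeRole.NUCLEOPHILE
        return None


@dataclass
class ReactionFeatureTable:
    """Reactions × numeric descriptors with per-feature role metadata.

    Parameters
    ----------
    reaction_ids
        One identifier per row.
    features
        ``(n_reactions, n_features)`` float matrix; all values finite.
    feature_names
        Unique column names, one per matrix column.
    feature_roles
        Mapping feature name → :class:`MoleculeRole`; must cover every
        feature.
    target
        Optional ΔΔG‡ vector (kcal/mol), one value per reaction.
    source_label
        Free-form provenance tag (e.g. a reaction-type group name).
    """

    reaction_ids: list[str]
    features: np.ndarray
    feature_names: list[str]
    feature_roles: dict[str, MoleculeRole]
    target: np.ndarray | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DataError("features must be a 2-d matrix")
        n, d = self.features.shape
        if len(self.reaction_ids) != n:
            raise DataError(f"{len(self.reaction_ids)} ids for {n} rows")
        if len(self.feature_names) != d:
            raise SchemaError(f"{len(self.feature_names)} names for {d} columns")
        if len(set(self.feature_names)) != d:
            raise SchemaError("feature names are not unique")
        for name in self.feature_names:
            if name not in self.feature_roles:
                raise SchemaError(f"no molecule role for feature {name!r}")
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise DataError(
                f"non-finite value at row {self.reaction_ids[bad[0]]!r}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (n,):
                raise DataError("target length must equal number of reactions")
            if not np.all(np.isfinite(self.target)):
                raise DataError("non-finite target value")

    # -- convenience -----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def role_counts(self) -> dict[MoleculeRole, int]:
        counts = {role: 0 for role in MoleculeRole}
        for name in self.feature_names:
            counts[self.feature_roles[name]] += 1
        return counts

    def features_by_role(self, role: MoleculeRole) -> list[str]:
        return [n for n in self.feature_names if self.feature_roles[n] is role]

    def column_matrix(self, names: list[str]) -> np.ndarray:
        """Columns in the given order; raises SchemaError on a missing name."""
        index = {n: j for j, n in enumerate(self.feature_names)}
        cols = []
        for name in names:
            if name not in index:
                raise SchemaError(f"feature {name!r} not present in table")
            cols.append(index[name])
        return self.features[:, cols]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, ID_COLUMN, self.reaction_ids)
        if self.target is not None:
            df[TARGET_COLUMN] = self.target
        return df


@dataclass
class TargetScreenReport:
    """Shapiro–Wilk normality and z-score outlier screen of ΔΔG‡."""

    shapiro_p: float
    z_min: float
    z_max: float
    outlier_ids: list[str] = field(default_factory=list)

    @property
    def has_outliers(self) -> bool:
        return bool(self.outlier_ids)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_feature_table(data_path, meta_path, source_label: str = "") -> ReactionFeatureTable:
    """Read a feature-table CSV plus its (feature, role) metadata CSV.

    The data CSV has a header row, a leading ``reaction_id`` column, numeric
    descriptor columns, and optionally a trailing ``ddg`` target column.
    Every descriptor column must appear in the metadata file.
    """
    df = pd.read_csv(data_path, dtype={ID_COLUMN: str}, float_precision="round_trip")
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"data CSV lacks the {ID_COLUMN!r} column")
    meta = pd.read_csv(meta_path)
    if not {"feature", "role"}.issubset(meta.columns):
        raise SchemaError("metadata CSV needs 'feature' and 'role' columns")
    roles: dict[str, MoleculeRole] = {}
    for feat, role in zip(meta["feature"], meta["role"]):
        try:
            roles[str(feat)] = MoleculeRole(str(role))
        except ValueError as exc:
            raise SchemaError(f"unknown role {role!r} for feature {feat!r}") from exc

    feature_names = [c for c in df.columns if c not in (ID_COLUMN, TARGET_COLUMN)]
    for name in feature_names:
        if name not in roles:
            raise SchemaError(f"column {name!r} missing from role metadata")
        if len(df) and not pd.api.types.is_numeric_dtype(df[name]):
            raise DataError(f"column {name!r} contains non-numeric values")
    target = df[TARGET_COLUMN].to_numpy(float) if TARGET_COLUMN in df.columns else None
    return ReactionFeatureTable(
        reaction_ids=[str(r) for r in df[ID_COLUMN]],
        features=df[feature_names].to_numpy(float),
        feature_names=feature_names,
        feature_roles={n: roles[n] for n in feature_names},
        target=target,
        source_label=source_label,
    )


def write_feature_table(table: ReactionFeatureTable, data_path, meta_path) -> None:
    """Write the CSV pair readable by :func:`read_feature_table`.

    Values are emitted with ``repr`` round-trip precision so a read-back
    table is bit-equal.
    """
    table.to_dataframe().to_csv(data_path, index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "feature": table.feature_names,
            "role": [table.feature_roles[n].value for n in table.feature_names],
        }
    ).to_csv(meta_path, index=False)


def subset_by_view(table: ReactionFeatureTable, view: FeatureView) -> ReactionFeatureTable:
    """Drop the columns of the view's excluded role; order otherwise kept."""
    view = FeatureView(view)
    dropped = view.dropped_role
    if dropped is None:
        return table
    keep = [n for n in table.feature_names if table.feature_roles[n] is not dropped]
    return replace(
        table,
        features=table.column_matrix(keep),
        feature_names=keep,
        feature_roles={n: table.feature_roles[n] for n in keep},
    )


# ---------------------------------------------------------------------------
# ΔΔG‡ / e.r. conversion
# ---------------------------------------------------------------------------

def ddg_from_er(er: float, temperature_K: float) -> float:
    """ΔΔG‡ = −R·T·ln(e.r.) in kcal/mol."""
    if er <= 0:
        raise ValueError("enantiomeric ratio must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -R_KCAL * temperature_K * math.log(er)


def er_from_ddg(ddg: float, temperature_K: float) -> float:
    """Inverse of :func:`ddg_from_er`: e.r. = exp(−ΔΔG‡ / (R·T))."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return math.exp(-ddg / (R_KCAL * temperature_K))


# ---------------------------------------------------------------------------
# Target screening
# ---------------------------------------------------------------------------

def screen_target(
    target: np.ndarray, reaction_ids: list[str] | None = None
) -> TargetScreenReport:
    """Shapiro–Wilk normality test plus |z| > 3 outlier flagging.

    z-scores use the sample standard deviation (ddof=1).
    """
    y = np.asarray(target, dtype=float)
    if y.size < 3:
        raise DataError("target screen needs at least 3 values")
    sd = y.std(ddof=1)
    if sd == 0:
        raise DataError("target has zero variance")
    if reaction_ids is None:
        reaction_ids = [str(i) for i in range(y.size)]
    z = (y - y.mean()) / sd
    _, p = stats.shapiro(y)
    outliers = [rid for rid, zi in zip(reaction_ids, z) if abs(zi) > OUTLIER_Z]
    return TargetScreenReport(
        shapiro_p=float(p), z_min=float(z.min()), z_max=float(z.max()),
        outlier_ids=outliers,
    )
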