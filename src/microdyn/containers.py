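"""Core data containers and their plain-text serialization.

The two central objects are:

* :class:`FeatureTable` — a samples x features matrix with per-sample and
  per-feature metadata. It is the universal currency of preprocessing and
  differential testing. Missing measurements are ``NaN``; an optional boolean
  mask records which cells were filled by paired-minimum imputation.
* :class:`AllelePileup` — per-position allele counts (A, C, G, T) for one
  species in one sample, the input to strain-level dissimilarity.

Pairwise dissimilarity records, replacement calls, diet logs and test results
are plain :class:`pandas.DataFrame` objects with documented column sets; the
column-name constants below are the single source of truth for those schemas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

#: Metadata columns carried by a feature-table TSV alongside the feature columns.
SAMPLE_META_COLUMNS = ("participant_id", "timepoint", "arm", "assay", "batch")

#: Columns of a dissimilarity-record frame (see strains.dissimilarity_sets).
DISSIM_COLUMNS = (
    "species_id",
    "sample_a",
    "sample_b",
    "participant_a",
    "participant_b",
    "n_comparable",
    "dissimilarity",
    "pair_type",
)

#: Columns of a replacement-call frame (see strains.call_replacements).
CALL_COLUMNS = (
    "participant_id",
    "species_id",
    "intra_dissimilarity",
    "threshold",
    "replaced",
)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class FeatureTable:
    """Samples x features matrix plus sample and feature metadata.

    Parameters
    ----------
    values
        Numeric matrix indexed by ``sample_id`` with feature ids as columns.
        Missing measurements are ``NaN``.
    sample_meta
        One row per sample (same index as ``values``) with at least
        ``participant_id`` and ``timepoint`` (``pre``/``post``); ``arm``,
        ``assay`` and ``batch`` columns are added with placeholder values if
        absent.
    feature_meta
        One row per feature (index matches ``values.columns``) with an
        ``assay`` column; built automatically if not given.
    imputed
        Boolean mask, same shape as ``values``, True where a cell was filled
        by imputation. Defaults to all-False.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"assay": "unknown"}, index=self.values.columns
            )
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        for col, default in (
            ("arm", "NA"),
            ("assay", "multi"),
            ("batch", 0),
        ):
            if col not in self.sample_meta.columns:
                self.sample_meta = self.sample_meta.assign(**{col: default})
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if not self.values.index.is_unique:
            raise InvalidInputError("sample ids must be unique")
        if not self.values.index.equals(self.sample_meta.index):
            raise InvalidInputError("values and sample_meta must share an index")
        if not self.values.columns.equals(self.feature_meta.index):
            raise InvalidInputError("values and feature_meta must share columns")
        key = self.sample_meta[["participant_id", "timepoint", "assay"]]
        if key.duplicated().any():
            raise InvalidInputError(
                "(participant_id, timepoint, assay) must be unique across samples"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy()).any():
                raise InvalidInputError("values must be finite or NaN")

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            self.imputed.copy(),
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            self.values[feature_ids],
            self.sample_meta,
            self.feature_meta.loc[feature_ids],
            self.imputed[feature_ids],
        )

    def features_for_assay(self, assay: str) -> list[str]:
        mask = self.feature_meta["assay"] == assay
        return list(self.feature_meta.index[mask])

    @property
    def assays(self) -> list[str]:
        return list(dict.fromkeys(self.feature_meta["assay"]))

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write samples x features TSV with leading metadata columns."""
        meta = self.sample_meta[list(SAMPLE_META_COLUMNS)]
        wide = pd.concat([meta, self.values], axis=1)
        wide.index.name = "sample_id"
        wide.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, feature_assays: pd.Series | None = None) -> "FeatureTable":
        wide = pd.read_csv(path, sep="\t", index_col="sample_id")
        meta_cols = [c for c in SAMPLE_META_COLUMNS if c in wide.columns]
        sample_meta = wide[meta_cols]
        values = wide.drop(columns=meta_cols)
        feature_meta = None
        if feature_assays is not None:
            feature_meta = pd.DataFrame(
                {"assay": feature_assays.reindex(values.columns)}
            )
        return cls(values, sample_meta, feature_meta)


@dataclass
class AllelePileup:
    """Per-position allele counts for one (species, sample).

    ``positions`` is a strictly increasing, 0-based integer array and
    ``counts`` the matching (n_positions, 4) array of A/C/G/T read counts.
    """

    species_id: str
    sample_id: str
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise InvalidInputError("counts must have shape (n_positions, 4)")
        if self.counts.shape[0] != self.positions.shape[0]:
            raise InvalidInputError("positions and counts must align")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise InvalidInputError("positions must be strictly increasing")
        if (self.counts < 0).any():
            raise InvalidInputError("allele counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per position."""
        return self.counts.sum(axis=1)

    @classmethod
    def from_position_map(cls, species_id, sample_id, position_map) -> "AllelePileup":
        """Build from a ``{position: (nA, nC, nG, nT)}`` mapping."""
        positions = np.array(sorted(position_map), dtype=np.int64)
        counts = np.array([position_map[p] for p in positions], dtype=np.int64)
        if counts.size == 0:
            counts = counts.reshape(0, 4)
        return cls(species_id, sample_id, positions, counts)


def write_pileups(pileups, path) -> None:
    """Serialize pileups to TSV (one row per covered position).

    Columns: species_id, sample_id, position, count_A..count_T.
    Positions are 0-based (declared in a header comment).
    """
    frames = []
    for p in pileups:
        frames.append(
            pd.DataFrame(
                {
                    "species_id": p.species_id,
                    "sample_id": p.sample_id,
                    "position": p.positions,
                    **{
                        f"count_{n}": p.counts[:, i]
                        for i, n in enumerate(NUCLEOTIDES)
                    },
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# positions are 0-based\n")
        table.to_csv(fh, sep="\t", index=False)


def read_pileups(path) -> list[AllelePileup]:
    table = pd.read_csv(path, sep="\t", comment="#")
    out = []
    count_cols = [f"count_{n}" for n in NUCLEOTIDES]
    for (sp, sm), grp in table.groupby(["species_id", "sample_id"], sort=False):
        grp = grp.sort_values("position")
        out.append(
            AllelePileup(
                str(sp),
                str(sm),
                grp["position"].to_numpy(),
                grp[count_cols].to_numpy(),
            )
        )
    return out


@dataclass
class MediationResult:
    """Path coefficients and bootstrap p-values for one (X, M, Y) triplet.

    ``indirect`` is always ``a * b``; ``significant`` follows the two-path
    rule: both the predictor->mediator path (a) and the mediator->outcome
    path given the predictor (b) must have bootstrap p < alpha.
    """

    predictor_id: str
    mediator_id: str
    outcome_id: str
    a: float
    b: float
    c_prime: float
    indirect: float
    p_a: float
    p_b: float
    p_indirect: float
    significant: bool
    mode: str = "signed_change"
    n: int = 0
    draws: dict | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("draws")
        return d


@dataclass
class DeltaEvaluation:
    """Agreement between observed and predicted metabolite change."""

    stratum: str  # "well_predicted" or "poorly_predicted"
    arm: str  # "PPT", "MED" or "both"
    pearson_r: float
    p: float
    variance_explained_percent: float
    n_metabolites: int
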