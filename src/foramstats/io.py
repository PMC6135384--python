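"""Tabular input/output and the shared domain types.

Three tables drive every analysis stage: a samples x taxa abundance matrix
(counts or percent abundances), a per-taxon annotation table (functional
group and test wall type), and a per-sample environmental table (depth,
satellite-derived means and mean anomalies, carbonate chemistry, specimen
totals).  All files are plain comma-separated UTF-8 with "." decimals.

A packaged Galapagos data set (19 samples from 7 islands, the 28 dominant
taxa) is available through :func:`load_galapagos`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AssemblageMatrix",
    "TaxonAnnotation",
    "SampleEnvironment",
    "AnalysisConfig",
    "read_assemblage",
    "write_assemblage",
    "read_taxa",
    "write_taxa",
    "read_environment",
    "write_environment",
    "environment_frame",
    "join_environment",
    "island_of",
    "load_galapagos",
    "load_galapagos_reference",
    "FUNCTIONAL_GROUPS",
    "WALL_TYPES",
]

FUNCTIONAL_GROUPS = ("symbiont_bearing", "opportunistic", "heterotrophic", "unknown")
WALL_TYPES = ("hyaline", "porcellaneous", "agglutinated", "unknown")

#: Environmental covariate columns used by ordination and the partition tree,
#: in canonical order (depth is appended only when configured).
ENV_VARIABLES = (
    "mean_chl",
    "mean_sst",
    "mean_sss",
    "omega_arag",
    "chl_anom",
    "sst_anom",
    "sss_anom",
    "pH",
)


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AssemblageMatrix:
    """Samples x taxa abundance table, the central community object.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with taxon ids as columns; values are
        nonnegative abundances.
    mode :
        ``"counts"`` for raw specimen counts, ``"percent"`` for per-sample
        percent abundances (row sums at most 100).  The mode is always
        explicit, never inferred.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "percent"):
            raise ValidationError(f"mode must be 'counts' or 'percent', got {self.mode!r}")
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("assemblage matrix needs at least 1 sample and 1 taxon")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if self.mode == "percent":
            sums = values.sum(axis=1)
            bad = np.nonzero(sums > 100.0 + 1e-6)[0]
            if bad.size:
                raise ValidationError(
                    f"percent-mode row sum exceeds 100 for sample {df.index[bad[0]]!r} "
                    f"({sums[bad[0]]:.6f})"
                )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, sample_id) -> pd.Series:
        return self.data.loc[sample_id]

    def merge_taxa(self, taxon_ids: Sequence, new_id) -> "AssemblageMatrix":
        """Sum a set of columns into one (e.g. pooling indeterminate taxa)."""
        missing = [t for t in taxon_ids if t not in self.data.columns]
        if missing:
            raise ValidationError(f"cannot merge unknown taxa: {missing}")
        keep = self.data.drop(columns=list(taxon_ids))
        merged = self.data[list(taxon_ids)].sum(axis=1)
        keep[new_id] = merged
        return AssemblageMatrix(keep, mode=self.mode)


@dataclass(frozen=True)
class TaxonAnnotation:
    """Functional-group and wall-type assignment for one taxon."""

    taxon_id: str
    functional_group: str
    wall_type: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValidationError(
                f"unknown functional group {self.functional_group!r} for taxon "
                f"{self.taxon_id!r}; allowed: {', '.join(FUNCTIONAL_GROUPS)}"
            )
        if self.wall_type not in WALL_TYPES:
            raise ValidationError(
                f"unknown wall type {self.wall_type!r} for taxon {self.taxon_id!r}; "
                f"allowed: {', '.join(WALL_TYPES)}"
            )


@dataclass(frozen=True)
class SampleEnvironment:
    """Per-sample environmental covariates (one row of the site table)."""

    sample_id: str
    lat: float
    lon: float
    depth: float
    mean_chl: float
    mean_sst: float
    mean_sss: float
    omega_arag: float
    chl_anom: float
    sst_anom: float
    sss_anom: float
    pH: float
    n_specimens: int

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValidationError(f"sample {self.sample_id!r}: depth must be > 0")
        if self.n_specimens < 0:
            raise ValidationError(f"sample {self.sample_id!r}: n_specimens must be >= 0")
        if not (6.0 < self.pH < 9.0):
            raise ValidationError(f"sample {self.sample_id!r}: pH {self.pH} outside (6, 9)")
        if not self.omega_arag > 0:
            raise ValidationError(f"sample {self.sample_id!r}: omega_arag must be > 0")


@dataclass
class AnalysisConfig:
    """Knobs shared across the pipeline stages.

    ``hellinger_sqrt`` selects the square-root (true Hellinger) transform;
    ``ward_variant`` chooses the Ward flavour ("D2": Lance-Williams on squared
    distances with heights reported in original units, "D": on raw distances);
    ``fi_site_averaging`` picks how sample FORAM-Index values aggregate to a
    site value; ``merge_unidentified`` pools the Usp1-4 columns before
    ordination as a single agglutinated group.
    """

    hellinger_sqrt: bool = True
    ward_variant: str = "D2"
    cut_k: int = 5
    n_permutations: int = 999
    rng_seed: int = 0
    tree_min_node: int = 2
    tree_min_deviance_fraction: float = 0.01
    fi_site_averaging: str = "mean_of_sample_fi"
    merge_unidentified: bool = False
    include_depth: bool = False
    site_scores: str = "wa"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.cut_k is not None and self.cut_k < 1:
            raise ValidationError("cut_k must be >= 1")
        if self.ward_variant not in ("D2", "D"):
            raise ValidationError("ward_variant must be 'D2' or 'D'")
        if self.fi_site_averaging not in ("mean_of_sample_fi", "pooled_counts"):
            raise ValidationError(
                "fi_site_averaging must be 'mean_of_sample_fi' or 'pooled_counts'"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc


def read_assemblage(path, mode: str = "counts") -> AssemblageMatrix:
    """Read a samples x taxa abundance CSV.

    The header row carries taxon ids and the first column carries sample ids.
    Input row and column order is preserved.
    """
    raw = _read_csv(path)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no samples")
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: no taxa columns")
    df = raw.set_index(raw.columns[0])
    df.index.name = "sample_id"
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at sample {df.index[i]!r}, taxon {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    if body.isna().to_numpy().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    return AssemblageMatrix(body, mode=mode)


def write_assemblage(matrix: AssemblageMatrix, path) -> None:
    # default float repr is shortest-exact, so write/read round-trips bitwise
    matrix.data.to_csv(path)


def read_taxa(path) -> list[TaxonAnnotation]:
    """Read taxon annotations (columns taxon_id, functional_group, wall_type)."""
    df = _read_csv(path)
    required = ["taxon_id", "functional_group", "wall_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    records = []
    seen = set()
    for _, r in df.iterrows():
        tid = str(r["taxon_id"])
        if tid in seen:
            raise ValidationError(f"{path}: duplicate taxon_id {tid!r}")
        seen.add(tid)
        records.append(
            TaxonAnnotation(
                taxon_id=tid,
                functional_group=str(r["functional_group"]),
                wall_type=str(r["wall_type"]),
                display_name=str(r.get("display_name", "") or ""),
            )
        )
    return records


def write_taxa(records: Iterable[TaxonAnnotation], path) -> None:
    pd.DataFrame([asdict(t) for t in records]).to_csv(path, index=False)


_ENV_REQUIRED = [
    "sample_id", "lat", "lon", "depth", "mean_chl", "mean_sst", "mean_sss",
    "omega_arag", "chl_anom", "sst_anom", "sss_anom", "n_specimens", "pH",
]


def read_environment(path) -> list[SampleEnvironment]:
    """Read the per-sample environmental table."""
    df = _read_csv(path)
    missing = [c for c in _ENV_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, r in df.iterrows():
        records.append(
            SampleEnvironment(
                sample_id=str(r["sample_id"]),
                lat=float(r["lat"]),
                lon=float(r["lon"]),
                depth=float(r["depth"]),
                mean_chl=float(r["mean_chl"]),
                mean_sst=float(r["mean_sst"]),
                mean_sss=float(r["mean_sss"]),
                omega_arag=float(r["omega_arag"]),
                chl_anom=float(r["chl_anom"]),
                sst_anom=float(r["sst_anom"]),
                sss_anom=float(r["sss_anom"]),
                pH=float(r["pH"]),
                n_specimens=int(r["n_specimens"]),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return records


def write_environment(records: Iterable[SampleEnvironment], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def environment_frame(records: Iterable[SampleEnvironment]) -> pd.DataFrame:
    """Environmental records as a DataFrame indexed by sample id."""
    df = pd.DataFrame([asdict(r) for r in records]).set_index("sample_id")
    return df


def join_environment(
    assemblage: AssemblageMatrix,
    records: Iterable[SampleEnvironment],
    variables: Sequence[str] = ENV_VARIABLES,
    include_depth: bool = False,
) -> pd.DataFrame:
    """Environmental covariates aligned to the assemblage's sample order.

    Fails loudly if any sample id of either table is unmatched.
    """
    env = environment_frame(records)
    a_ids = set(assemblage.sample_ids)
    e_ids = set(env.index)
    if a_ids != e_ids:
        only_a = sorted(a_ids - e_ids)
        only_e = sorted(e_ids - a_ids)
        raise ValidationError(
            f"sample id mismatch between assemblage and environment: "
            f"assemblage-only={only_a}, environment-only={only_e}"
        )
    cols = list(variables) + (["depth"] if include_depth and "depth" not in variables else [])
    return env.loc[assemblage.sample_ids, cols]


def island_of(sample_id: str) -> str:
    """Island/site code from a sample id (``'IS_EB-121' -> 'IS'``)."""
    return str(sample_id).split("-")[0].split("_")[0]


# ---------------------------------------------------------------------------
# packaged Galapagos data set
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("foramstats.data").joinpath(name)


def load_galapagos() -> tuple[AssemblageMatrix, list[TaxonAnnotation], list[SampleEnvironment]]:
    """The packaged Galapagos survey: percent abundances of the 28 dominant
    taxa in 19 samples, taxon annotations, and the per-sample environment."""
    assemblage = read_assemblage(_data_path("galapagos_assemblage.csv"), mode="percent")
    taxa = read_taxa(_data_path("galapagos_taxa.csv"))
    env = read_environment(_data_path("galapagos_environment.csv"))
    return assemblage, taxa, env


def load_galapagos_reference() -> pd.DataFrame:
    """Published per-sample diversity summary (S, N, Fisher alpha, FORAM-Index)
    for the Galapagos survey, used as cross-check targets."""
    return pd.read_csv(_data_path("galapagos_diversity_reference.csv")).set_index("sample_id")
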