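"""Core data model: abundance, taxonomy, environment and metadata tables.

Every analysis stage consumes these containers. An :class:`AbundanceTable`
is a samples x species matrix of non-negative individual counts (direct
morphospecies enumeration, not sequence reads) together with per-sample
metadata (ecosystem, season, coordinates, altitude). A
:class:`TaxonomyTable` resolves each morphospecies to a four-rank lineage
(genus, family, order, class); an :class:`EnvTable` holds the measured soil
physicochemical factors per sample.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXONOMY_RANKS = ("genus", "family", "order", "class")

#: Soil physicochemical factors measured in the field campaign.
ENV_FACTORS = ("SWC", "pH", "TN", "SOM", "AP", "RAK", "ST")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how the study tables print percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AbundanceTable:
    """Samples x species count matrix with optional per-sample metadata.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample ID with species IDs as columns;
        cells are non-negative counts of individuals.
    metadata:
        Optional DataFrame indexed by sample ID. Recognised columns:
        ``ecosystem``, ``season``, ``latitude``, ``longitude``, ``altitude``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise ValidationError("abundance table is empty")
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species IDs: {dup}")
        vals = c.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("abundance table contains non-numeric cells")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[i]!r}, species {c.columns[j]!r}"
            )
        if self.metadata is not None:
            missing = c.index.difference(self.metadata.index)
            if len(missing):
                raise ValidationError(f"samples missing from metadata: {list(missing)}")
            self.metadata = self.metadata.loc[c.index]

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def groups(self, by: str) -> pd.Series:
        """Per-sample group labels, e.g. ``by='ecosystem'`` or ``'season'``."""
        if self.metadata is None or by not in self.metadata.columns:
            raise ValidationError(f"metadata column {by!r} not available")
        return self.metadata[by]

    def subset(self, samples: list[str] | pd.Index) -> "AbundanceTable":
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return AbundanceTable(self.counts.loc[samples], meta)

    def relativize(self) -> pd.DataFrame:
        """Relative abundances per sample (rows sum to 1)."""
        tot = self.counts.sum(axis=1)
        if (tot == 0).any():
            bad = tot.index[tot == 0].tolist()
            raise ValidationError(f"zero-total samples: {bad}")
        return self.counts.div(tot, axis=0)


@dataclass
class TaxonomyTable:
    """Species -> (genus, family, order, class) lineage map.

    Rank consistency is enforced: a family belongs to exactly one order and
    an order to exactly one class.
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species in taxonomy: {dup}")
        if df[list(TAXONOMY_RANKS)].isna().any().any() or (
            df[list(TAXONOMY_RANKS)].astype(str) == ""
        ).any().any():
            raise ValidationError("taxonomy contains empty rank entries")
        for child, parent in (("family", "order"), ("order", "class")):
            n_parents = df.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1].index.tolist()
            if bad:
                raise ValidationError(
                    f"inconsistent ranks: {child} values {bad} map to multiple {parent}s"
                )

    @property
    def species(self) -> list[str]:
        return list(self.lineages.index)

    def rank_of(self, species: list[str], rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {TAXONOMY_RANKS}")
        unmapped = [s for s in species if s not in self.lineages.index]
        if unmapped:
            raise ValidationError(f"species not in taxonomy: {unmapped}")
        return self.lineages.loc[species, rank]


@dataclass
class EnvTable:
    """Sample -> soil physicochemical factors (SWC %, pH, TN g/kg, SOM g/kg,
    AP mg/kg, RAK mg/kg, ST degC, altitude m). Missing cells are allowed and
    propagate as exclusion from pairwise analyses."""

    factors: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.factors
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in environmental table")
        if "SWC" in df.columns:
            swc = df["SWC"].dropna()
            if ((swc < 0) | (swc > 100)).any():
                raise ValidationError("SWC must lie in [0, 100] percent by mass")
        if "pH" in df.columns:
            ph = df["pH"].dropna()
            if ((ph < 0) | (ph > 14)).any():
                raise ValidationError("pH must lie in [0, 14]")
        for col in ("TN", "SOM", "AP", "RAK"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValidationError(f"{col} must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.factors.index)

    def aligned_to(self, ab: AbundanceTable) -> pd.DataFrame:
        missing = pd.Index(ab.samples).difference(self.factors.index)
        if len(missing):
            raise ValidationError(f"environmental table lacks samples: {list(missing)}")
        return self.factors.loc[ab.samples]


# ---------------------------------------------------------------------------
# Readers / writers (CSV/TSV, UTF-8)
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_abundance(
    path: str | Path,
    dialect: str | None = None,
    orientation: str = "samples_rows",
    metadata: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Read a delimited abundance matrix.

    Canonical orientation is samples as rows / species as columns;
    ``orientation='species_rows'`` transposes on read. Blank cells are true
    zeros (absence in a culture count is absence, not missingness).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path} is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path} contains no data rows/columns")
    if orientation == "species_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = df.apply(pd.to_numeric, errors="coerce").fillna(0.0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, metadata=metadata)


def write_abundance(ab: AbundanceTable, path: str | Path, dialect: str | None = None) -> None:
    ab.counts.to_csv(path, sep=_sep_for(path, dialect))


def read_taxonomy(path: str | Path, dialect: str | None = None) -> TaxonomyTable:
    """Read a taxonomy table with columns species,genus,family,order,class."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols:
        raise ValidationError("taxonomy file needs a 'species' column")
    df = df.rename(columns={v: k for k, v in cols.items()}).set_index("species")
    return TaxonomyTable(df)


def read_env(path: str | Path, dialect: str | None = None) -> EnvTable:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    return EnvTable(df.apply(pd.to_numeric, errors="coerce"))


def read_metadata(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# Composition summaries
# ---------------------------------------------------------------------------

def summarize_composition(
    ab: AbundanceTable, tax: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Distinct-species counts per taxon at a rank, with percent of total.

    Percentages are of distinct species (100 * species_count / total observed
    species), rounded half-up to 2 decimals as the study tables print them.
    Species present in the taxonomy but absent from the abundance table are
    ignored with a warning.
    """
    observed = [s for s in ab.species if ab.counts[s].sum() > 0]
    extra = set(tax.species) - set(ab.species)
    if extra:
        logger.warning("%d taxonomy species absent from abundance table", len(extra))
    labels = tax.rank_of(observed, rank)
    counts = labels.groupby(labels).size().sort_values(ascending=False)
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "taxon": counts.index,
            "species_count": counts.to_numpy(),
            "percent_of_total": [round_half_up(100.0 * c / total) for c in counts],
        }
    ).reset_index(drop=True)
    return out


def shared_species(ab: AbundanceTable, group_by: str) -> pd.DataFrame:
    """Exhaustive disjoint-subset species counts across groups (UpSet-style).

    A species belongs to the subset of groups in which its summed count is
    positive. Counts over all non-empty subsets sum to the number of species
    with a non-zero total.
    """
    labels = ab.groups(group_by)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError(f"need >=2 groups to intersect, got {groups}")
    presence = {}
    for g in groups:
        sub = ab.counts.loc[labels[labels == g].index]
        presence[g] = sub.sum(axis=0) > 0
    pres = pd.DataFrame(presence)  # species x groups boolean
    rows = []
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            mask = np.ones(len(pres), dtype=bool)
            for g in groups:
                want = g in subset
                mask &= pres[g].to_numpy() == want
            rows.append(
                {
                    "groups": "&".join(subset),
                    "n_groups": r,
                    "species_count": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)
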