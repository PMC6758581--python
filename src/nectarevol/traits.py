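"""Species trait vectors, pollination-syndrome labels and trait transforms.

Continuous nectar traits are analysed on a transformed scale: volumes and
amino-acid concentrations on the natural-log scale, percentages and
proportions on the logit scale (with a small additive offset when zeros
occur).  :class:`TraitVector` records the transform so downstream results
(optima, confidence intervals) can be reported back on the natural scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SYNDROMES",
    "SYNDROME_ORDER",
    "TraitVector",
    "SyndromeMap",
    "transform",
    "inverse_transform",
    "read_trait_table",
    "TraitError",
]

# The five pollinator syndrome classes.  SYNDROME_ORDER fixes the regime /
# treatment-coding order used throughout (bird is the reference level).
SYNDROME_ORDER: tuple[str, ...] = (
    "bird",
    "butterfly",
    "bee",
    "fly",
    "bee_and_butterfly",
)
SYNDROMES = frozenset(SYNDROME_ORDER)


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class TraitVector:
    """Per-species values of one continuous trait.

    Attributes
    ----------
    values : pandas.Series
        Indexed by species label.
    name, units : str
        Trait label and measurement units (free text).
    transform : {"identity", "log", "logit"}
        Scale the values currently live on.
    offset : float
        Additive offset applied (on the proportion scale) before logit.
    percent : bool
        True if the natural scale is a percentage (divided by 100 before
        the logit; multiplied back on inverse transform).
    """

    values: pd.Series
    name: str = ""
    units: str = ""
    transform: str = "identity"
    offset: float = 0.0
    percent: bool = False

    def __post_init__(self):
        s = pd.Series(self.values, dtype=float)
        if s.index.has_duplicates:
            raise TraitError(f"duplicate species in trait {self.name!r}")
        object.__setattr__(self, "values", s)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def align_to(self, labels) -> "TraitVector":
        """Restrict to the given species, dropping (with a log note) the rest."""
        labels = [l for l in labels if l in self.values.index]
        dropped = set(self.values.index) - set(labels)
        if dropped:
            logger.warning(
                "trait %s: dropping %d species absent from tree/table: %s",
                self.name, len(dropped), sorted(dropped)[:5],
            )
        return replace(self, values=self.values.loc[labels])

    def to_array(self, order) -> np.ndarray:
        missing = [l for l in order if l not in self.values.index]
        if missing:
            raise TraitError(f"trait {self.name!r} missing species {missing[:5]}")
        return self.values.loc[list(order)].to_numpy()


@dataclass(frozen=True)
class SyndromeMap:
    """Species → pollination syndrome (one of the five classes)."""

    values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {sp: s for sp, s in self.values.items() if s not in SYNDROMES}
        if bad:
            sp, s = next(iter(bad.items()))
            raise TraitError(
                f"unknown pollination syndrome {s!r} for species {sp!r}; "
                f"allowed: {sorted(SYNDROMES)}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.values)

    def states_present(self) -> list[str]:
        present = set(self.values.values())
        return [s for s in SYNDROME_ORDER if s in present]

    def subset(self, labels) -> "SyndromeMap":
        return SyndromeMap({l: self.values[l] for l in labels})

    def __getitem__(self, sp: str) -> str:
        return self.values[sp]

    def __len__(self) -> int:
        return len(self.values)


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------
def transform(tv: TraitVector, kind: str, offset: float = 0.0,
              percent: bool | None = None) -> TraitVector:
    """Apply a log or logit transform, recording the metadata.

    Percentages are divided by 100 first (``percent=True``, the default when
    the trait units mention '%'); the offset is applied on the proportion
    scale.  Domain violations name the offending species.
    """
    if tv.transform != "identity":
        raise TraitError(f"trait {tv.name!r} is already on a {tv.transform} scale")
    x = tv.values.astype(float)
    if kind == "log":
        bad = x.index[~(x > 0)]
        if len(bad):
            raise TraitError(f"log transform of nonpositive value for {list(bad)[:5]}")
        out = np.log(x)
        return replace(tv, values=out, transform="log")
    if kind == "logit":
        if percent is None:
            percent = "%" in tv.units
        p = x / 100.0 if percent else x
        p = p + offset
        bad = p.index[~((p > 0) & (p < 1))]
        if len(bad):
            raise TraitError(
                f"logit transform outside (0,1) after offset {offset} for {list(bad)[:5]}"
            )
        out = np.log(p / (1.0 - p))
        return replace(tv, values=out, transform="logit", offset=offset,
                       percent=bool(percent))
    raise TraitError(f"unknown transform {kind!r}")


def inverse_transform(tv: TraitVector) -> TraitVector:
    """Back-transform to the natural scale (for reporting)."""
    return replace(tv, values=back_transform_values(tv.values, tv),
                   transform="identity", offset=0.0, percent=False)


def back_transform_values(y, tv: TraitVector):
    """Back-transform numbers from ``tv``'s scale to its natural scale."""
    y = np.asarray(y, dtype=float) if not isinstance(y, pd.Series) else y
    if tv.transform == "identity":
        return y
    if tv.transform == "log":
        return np.exp(y)
    if tv.transform == "logit":
        p = 1.0 / (1.0 + np.exp(-y)) - tv.offset
        return p * 100.0 if tv.percent else p
    raise TraitError(f"unknown transform {tv.transform!r}")


# ----------------------------------------------------------------------
# trait table I/O
# ----------------------------------------------------------------------
TRAIT_UNITS = {
    "volume_ul": "μL",
    "sugar_pct": "% w/w",
    "nsp_pct": "%",
    "aa_mm": "mM",
    "spur_mm": "mm",
    "total_spur_mm": "mm",
}


def read_trait_table(path) -> tuple[list[TraitVector], SyndromeMap]:
    """Read a species × trait CSV/TSV table.

    Expected columns: ``species``, ``syndrome``, then numeric trait columns
    (``volume_ul``, ``sugar_pct``, ``nsp_pct``, ``aa_mm``, ``aa_frac_*``,
    ``spur_mm``, ``total_spur_mm``; extra numeric columns are kept too).
    Replicate rows for a species (e.g. repeated nectar samples per flower)
    are averaged on the raw scale.  Missing cells drop that species from
    that trait only.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise TraitError(f"empty trait table: {path}")
    for col in ("species", "syndrome"):
        if col not in df.columns:
            raise TraitError(f"trait table must have a {col!r} column")
    bad = df[~df["syndrome"].isin(SYNDROMES)]
    if len(bad):
        row = bad.iloc[0]
        raise TraitError(
            f"unknown syndrome {row['syndrome']!r} for species {row['species']!r} "
            f"(row {bad.index[0] + 2} of {path})"
        )
    incons = df.groupby("species")["syndrome"].nunique()
    if (incons > 1).any():
        raise TraitError(
            f"inconsistent syndrome labels for species {list(incons[incons > 1].index)}"
        )
    trait_cols = [c for c in df.columns if c not in ("species", "syndrome")]
    for c in trait_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise TraitError(f"non-numeric value in trait column {c!r}: {exc}") from exc
    n_rows = len(df)
    agg = df.groupby("species", sort=False)[trait_cols].mean()
    if len(agg) < n_rows:
        logger.info("averaged %d replicate rows into %d species", n_rows, len(agg))
    syn = SyndromeMap(
        df.drop_duplicates("species").set_index("species")["syndrome"].to_dict()
    )
    vectors = []
    for c in trait_cols:
        s = agg[c].dropna()
        if s.empty:
            warnings.warn(f"trait column {c!r} has no data; skipped")
            continue
        if len(s) < len(agg):
            logger.info("trait %s: %d species without data dropped", c, len(agg) - len(s))
        vectors.append(TraitVector(s, name=c, units=TRAIT_UNITS.get(c, "")))
    return vectors, syn


def write_trait_table(path, vectors: list[TraitVector], syn: SyndromeMap,
                      header_comment: str | None = None) -> None:
    """Write the companion CSV for a trait bundle (one row per species)."""
    species = list(syn.values)
    df = pd.DataFrame({"species": species, "syndrome": [syn[s] for s in species]})
    for tv in vectors:
        df[tv.name] = [tv.values.get(s, np.nan) for s in species]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
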