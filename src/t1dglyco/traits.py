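"""Peak annotation schemas and derived glycosylation traits.

The plasma panel has 39 HILIC-UPLC peaks (GP1-GP39) and 15 derived traits,
the IgG panel 24 peaks (GP1-GP24) and 9 derived traits.  A derived trait is
the sum of the percentages of all peaks sharing a structural feature, e.g.
G1 sums all monogalactosylated complex peaks and HM all high-mannose peaks,
which keeps every trait a linear functional of the peak percentages.

The per-peak structure assignments shipped in ``data/`` follow the
convention of the HILIC-UPLC glycomics literature; peaks containing
co-eluting structures are assigned the features of the dominant structure
(noted in the table), and the tables are plain TSV so they can be edited
when an authoritative composition list is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tables import PeakTable

__all__ = [
    "PeakAnnotation",
    "PLASMA_TRAITS",
    "IGG_TRAITS",
    "load_peak_annotation",
    "plasma_annotation",
    "igg_annotation",
    "compute_derived_traits",
    "validate_schema",
]

#: Plasma derived traits: galactosylation G0-G4, sialylation S1-S4,
#: bisecting GlcNAc (B), antennary/core fucose (AF/CF), low/high branching
#: (LB = biantennary complex, HB = tri-/tetra-antennary) and high mannose.
PLASMA_TRAITS = (
    "G0", "G1", "G2", "G3", "G4",
    "S1", "S2", "S3", "S4",
    "B", "AF", "CF", "LB", "HB", "HM",
)

#: IgG derived traits (biantennary panel): G0-G2, S0-S2, B, CF, HM.
IGG_TRAITS = ("G0", "G1", "G2", "S0", "S1", "S2", "B", "CF", "HM")

FEATURE_COLUMNS = (
    "galactose_count",
    "sialic_count",
    "bisecting",
    "core_fucose",
    "antennary_fucose",
    "branching",
    "high_mannose",
)


class SchemaError(ValueError):
    """Annotation table violates a structural invariant."""


@dataclass
class PeakAnnotation:
    """Validated per-peak structural features for one panel."""

    table: pd.DataFrame
    kind: str  # "plasma" | "igg" | "custom"

    @property
    def peak_ids(self) -> list:
        return list(self.table["peak_id"])

    @property
    def n_peaks(self) -> int:
        return len(self.table)

    @property
    def trait_names(self) -> tuple:
        if self.kind == "igg":
            return IGG_TRAITS
        return PLASMA_TRAITS

    def members(self, trait: str) -> list:
        """Peak ids carrying the feature that defines ``trait``."""
        mask = _trait_mask(self.table, trait)
        return list(self.table.loc[mask, "peak_id"])


def _trait_mask(df: pd.DataFrame, trait: str) -> np.ndarray:
    hm = df["high_mannose"].astype(bool).to_numpy()
    gal = df["galactose_count"].to_numpy()
    sia = df["sialic_count"].to_numpy()
    if trait == "HM":
        return hm
    if trait == "B":
        return df["bisecting"].astype(bool).to_numpy()
    if trait == "CF":
        return df["core_fucose"].astype(bool).to_numpy()
    if trait == "AF":
        return df["antennary_fucose"].astype(bool).to_numpy()
    if trait == "LB":
        return ~hm & (df["branching"].to_numpy() == "low")
    if trait == "HB":
        return ~hm & (df["branching"].to_numpy() == "high")
    if trait.startswith("G"):
        # agalactosylated (G0) excludes high-mannose by convention
        return ~hm & (gal == int(trait[1]))
    if trait.startswith("S"):
        return ~hm & (sia == int(trait[1]))
    raise ValueError(f"unknown trait {trait!r}")


def load_peak_annotation(source, kind: str = "custom") -> PeakAnnotation:
    """Load and validate a peak annotation table.

    ``source`` is a TSV path or a DataFrame with columns ``peak_id``,
    ``structure_label`` and the feature columns.  Structural invariants are
    enforced: a high-mannose peak carries no galactose, sialic acid or
    fucose, and a complex peak cannot have more sialic acids than
    galactoses.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    required = ("peak_id", "structure_label") + FEATURE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation missing columns: {missing}")
    if df["peak_id"].duplicated().any():
        raise SchemaError("duplicate peak ids in annotation")

    problems = []
    for _, row in df.iterrows():
        pid = row["peak_id"]
        if row["branching"] not in ("low", "high"):
            problems.append(f"{pid}: unknown branching code {row['branching']!r}")
        if not (0 <= row["galactose_count"] <= 4 and 0 <= row["sialic_count"] <= 4):
            problems.append(f"{pid}: counts must lie in 0..4")
        if row["high_mannose"]:
            if (
                row["galactose_count"] != 0
                or row["sialic_count"] != 0
                or row["core_fucose"]
                or row["antennary_fucose"]
            ):
                problems.append(
                    f"{pid}: high-mannose peak cannot carry galactose, "
                    "sialic acid or fucose"
                )
        elif row["sialic_count"] > row["galactose_count"]:
            problems.append(f"{pid}: sialic_count > galactose_count on complex peak")
    if problems:
        raise SchemaError("invalid annotation rows:\n  " + "\n  ".join(problems))
    return PeakAnnotation(table=df.reset_index(drop=True), kind=kind)


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("t1dglyco.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def plasma_annotation() -> PeakAnnotation:
    """The shipped 39-peak plasma panel annotation."""
    return load_peak_annotation(_packaged("plasma_peaks.tsv"), kind="plasma")


def igg_annotation() -> PeakAnnotation:
    """The shipped 24-peak IgG panel annotation."""
    return load_peak_annotation(_packaged("igg_peaks.tsv"), kind="igg")


def compute_derived_traits(table: PeakTable, annotation: PeakAnnotation) -> pd.DataFrame:
    """Derived glycosylation traits per sample.

    Each trait is the sum of the percent-state values of its member peaks,
    computed on the percent table (traits are interpretable shares of the
    total chromatogram, so they are never computed on rank-normalized
    values).  Returns a samples x traits DataFrame.
    """
    table.require_state("percent")
    have = set(table.peak_ids)
    want = set(annotation.peak_ids)
    if have != want:
        raise ValueError(
            "peak mismatch between table and annotation; "
            f"only in table: {sorted(have - want)}, only in annotation: {sorted(want - have)}"
        )
    df = table.values[annotation.peak_ids]
    out = {}
    for trait in annotation.trait_names:
        mask = _trait_mask(annotation.table, trait)
        out[trait] = df.loc[:, mask].sum(axis=1)
    return pd.DataFrame(out, index=table.values.index)


def validate_schema(annotation: PeakAnnotation, expected_kind: str) -> dict:
    """Check a schema against the expected panel shape.

    plasma: 39 peaks and 15 derivable traits; igg: 24 peaks and 9 traits.
    A trait is derivable when at least one peak carries its feature.
    Returns a report dict; failures are carried in the report, not raised.
    """
    if expected_kind == "plasma":
        expected_peaks, trait_names = 39, PLASMA_TRAITS
    elif expected_kind == "igg":
        expected_peaks, trait_names = 24, IGG_TRAITS
    else:
        raise ValueError("expected_kind must be 'plasma' or 'igg'")
    derivable = [t for t in trait_names if _trait_mask(annotation.table, t).any()]
    failures = []
    if annotation.n_peaks != expected_peaks:
        failures.append(
            f"expected {expected_peaks} peaks, found {annotation.n_peaks}"
        )
    if len(derivable) != len(trait_names):
        missing = sorted(set(trait_names) - set(derivable))
        failures.append(f"traits without member peaks: {missing}")
    return {
        "kind": expected_kind,
        "n_peaks": annotation.n_peaks,
        "n_traits": len(derivable),
        "expected_peaks": expected_peaks,
        "expected_traits": len(trait_names),
        "derivable_traits": derivable,
        "passed": not failures,
        "failures": failures,
    }
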