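"""Relative quantification from precursor peak areas.

Three summaries, all compositional (rows close to 100%):

* form compositions — the relative abundance of each modified form of one
  peptide region of one variant, from the ratio of its precursor peak area
  to the total area of that peptide sequence;
* variant proportions — the share of each variant within a family, from the
  mean area of its unique peptides over the family total;
* mark-level abundances — K27/K36 methylation marks aggregated across the
  H3.1 and H3.3 variants weighted by the variant mixture.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDataError, SchemaError, UndefinedRatioError

logger = logging.getLogger(__name__)

AREA_COLUMNS = ["sample_id", "peptide_sequence", "modifications", "charge", "area"]
META_COLUMNS = ["sample_id", "genotype", "treatment", "replicate"]

GENOTYPES = ("WT", "fas1", "fas1_m123_2", "m123_2")
TREATMENTS = ("control", "zeocin")

UNMODIFIED = "unmodified"

_MARK_RE = re.compile(r"^([A-Z])(\d+)(ac|me1|me2|me3|ph)$")


@dataclass(frozen=True)
class VariantMixture:
    """Fractions of H3.1 and H3.3 in the H3 pool; they sum to 1."""

    f_h31: float
    f_h33: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_h31 <= 1.0 and 0.0 <= self.f_h33 <= 1.0):
            raise InvalidDataError("mixture fractions must lie in [0, 1]")
        if abs(self.f_h31 + self.f_h33 - 1.0) > 1e-12:
            raise InvalidDataError("mixture fractions must sum to 1")


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def normalize_form_id(modifications: object) -> str:
    """Canonical form label: sorted semicolon-joined tokens or 'unmodified'."""
    if modifications is None or pd.isna(modifications):
        return UNMODIFIED
    s = str(modifications).strip()
    if not s or s == UNMODIFIED:
        return UNMODIFIED
    tokens = [t.strip() for t in s.split(";") if t.strip()]
    tokens.sort(key=lambda t: (int(_MARK_RE.match(t).group(2)) if _MARK_RE.match(t) else 0, t))
    return ";".join(tokens)


def collapse_charge_states(table: pd.DataFrame) -> pd.DataFrame:
    """Sum areas of identical (sample, peptidoform) across charge states.

    Missing values are ignored when any charge state was observed; a
    peptidoform missing in every charge state stays missing.
    """
    _check_columns(table, AREA_COLUMNS, "peak-area table")
    if (table["area"].dropna() < 0).any():
        raise InvalidDataError("negative peak area")
    df = table.copy()
    df["form_id"] = df["modifications"].map(normalize_form_id)
    out = (
        df.groupby(["sample_id", "peptide_sequence", "form_id"], sort=False)["area"]
        .sum(min_count=1)
        .reset_index()
    )
    return out


def form_relative_abundance(
    collapsed: pd.DataFrame, peptide_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample relative abundance (%) of each modified form of a region.

    A region is one peptide sequence of one variant (group). Parts are
    100 x area / total observed area of the region in that sample; forms
    missing in a sample stay missing (imputation is a separate step).
    Samples where every form of a region is missing are kept as all-missing
    rows with a warning.
    """
    _check_columns(collapsed, ["sample_id", "peptide_sequence", "form_id", "area"], "collapsed table")
    _check_columns(peptide_map, ["sequence", "groups", "start", "end", "unique"], "peptide map")
    pm = peptide_map.set_index("sequence")
    unknown = set(collapsed["peptide_sequence"]) - set(pm.index)
    if unknown:
        raise SchemaError(f"peptide sequences absent from the map: {sorted(unknown)[:5]}")

    df = collapsed.copy()
    df["variant"] = df["peptide_sequence"].map(pm["groups"])
    df["region"] = df.apply(
        lambda r: f"{r['variant']} {pm.loc[r['peptide_sequence'], 'start']}-"
        f"{pm.loc[r['peptide_sequence'], 'end']}",
        axis=1,
    )
    totals = df.groupby(["sample_id", "region"])["area"].transform(
        lambda s: s.sum(min_count=1)
    )
    df["percent"] = 100.0 * df["area"] / totals
    empty = df.groupby(["sample_id", "region"])["area"].transform(lambda s: s.notna().sum()) == 0
    if empty.any():
        for key in df.loc[empty, ["sample_id", "region"]].drop_duplicates().itertuples(index=False):
            logger.warning("all forms missing for sample %s region %s", key.sample_id, key.region)
    return df[["sample_id", "variant", "region", "peptide_sequence", "form_id", "percent"]]


def variant_proportions(
    collapsed: pd.DataFrame,
    peptide_map: pd.DataFrame,
    family_of_group: Mapping[str, str],
    family: str,
) -> pd.DataFrame:
    """Per-sample proportions (%) of each variant within one family.

    The score of a variant is the arithmetic mean over its unique peptides
    of the peptide's total area (modification states summed first); the
    proportion is the score over the family sum. Only variants with unique
    evidence participate.
    """
    pm = peptide_map[peptide_map["unique"]]
    pm = pm[pm["groups"].map(lambda g: family_of_group.get(g) == family)]
    if pm.empty:
        raise SchemaError(f"no unique peptides for family {family!r}")
    seq_to_variant = pm.set_index("sequence")["groups"]

    df = collapsed[collapsed["peptide_sequence"].isin(seq_to_variant.index)].copy()
    df["variant"] = df["peptide_sequence"].map(seq_to_variant)
    per_peptide = (
        df.groupby(["sample_id", "variant", "peptide_sequence"])["area"]
        .sum(min_count=1)
        .reset_index()
    )
    per_variant = (
        per_peptide.groupby(["sample_id", "variant"])["area"].mean().reset_index()
    )
    variants = sorted(seq_to_variant.unique())
    if len(variants) < 2:
        logger.warning("family %s has fewer than two quantifiable variants", family)
    totals = per_variant.groupby("sample_id")["area"].transform("sum")
    per_variant["percent"] = 100.0 * per_variant["area"] / totals
    per_variant["family"] = family
    return per_variant[["sample_id", "family", "variant", "percent"]]


def variant_pair_ratio(
    props: pd.DataFrame, a: str, b: str, meta: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-sample ratio a:b (b normalized to 1), optionally with genotype means."""
    wide = props.pivot(index="sample_id", columns="variant", values="percent")
    for v in (a, b):
        if v not in wide.columns:
            raise SchemaError(f"variant {v!r} not present in proportions table")
    if (wide[b] == 0).any():
        raise UndefinedRatioError(f"variant {b!r} has zero proportion in some sample")
    out = pd.DataFrame({"sample_id": wide.index, "ratio": (wide[a] / wide[b]).values})
    if meta is not None:
        out = out.merge(meta[["sample_id", "genotype"]], on="sample_id", how="left")
    return out


def mark_of_form(form_id: str, marks: Sequence[str]) -> list[str]:
    """Marks of interest carried by a form; empty list means unmodified."""
    if form_id == UNMODIFIED:
        return []
    return [t for t in form_id.split(";") if t in marks]


H3_MARKS = ("K27me1", "K27me2", "K27me3", "K36me1", "K36me2", "K36me3")


def mark_level_abundance(
    comp_h31: Mapping[str, float],
    comp_h33: Mapping[str, float],
    mixture: VariantMixture,
    marks: Sequence[str] = H3_MARKS,
) -> dict[str, float]:
    """Aggregate within-variant form compositions into mark-level percentages.

    Each form's variant-weighted abundance (mixture fraction x within-variant
    percent) contributes once to every mark category it carries; forms with
    no K27/K36 methylation contribute to 'unmodified'. Categories are then
    renormalized to 100%. Other modifications (K37, R methylation) fold into
    'unmodified' here but remain distinct forms upstream.
    """
    weights = {"H3.1": (mixture.f_h31, comp_h31), "H3.3": (mixture.f_h33, comp_h33)}
    acc: dict[str, float] = {m: 0.0 for m in marks}
    acc[UNMODIFIED] = 0.0
    for variant, (f_v, comp) in weights.items():
        for form_id, percent in comp.items():
            carried = mark_of_form(normalize_form_id(form_id), marks)
            w = f_v * percent
            if carried:
                for m in carried:
                    acc[m] += w
            else:
                acc[UNMODIFIED] += w
    total = sum(acc.values())
    if total <= 0:
        raise InvalidDataError("empty mark aggregation")
    return {k: 100.0 * v / total for k, v in acc.items()}


def mark_table(
    forms: pd.DataFrame,
    mixtures: Mapping[str, VariantMixture],
    h31_label: str = "H3.1",
    h33_label: str = "H3.3",
    marks: Sequence[str] = H3_MARKS,
) -> pd.DataFrame:
    """Mark-level abundances per sample from a form-composition table.

    ``mixtures`` maps sample_id to its H3.1/H3.3 mixture (e.g. from
    variant proportions).
    """
    rows = []
    for sample_id, sub in forms.groupby("sample_id"):
        comp31 = (
            sub[sub["variant"] == h31_label].set_index("form_id")["percent"].dropna().to_dict()
        )
        comp33 = (
            sub[sub["variant"] == h33_label].set_index("form_id")["percent"].dropna().to_dict()
        )
        if not comp31 or not comp33 or sample_id not in mixtures:
            continue
        agg = mark_level_abundance(comp31, comp33, mixtures[sample_id], marks)
        for mark, pct in agg.items():
            rows.append({"sample_id": sample_id, "mark": mark, "percent": pct})
    return pd.DataFrame(rows)


def read_area_table(path) -> pd.DataFrame:
    """Read a long-format peak-area CSV/TSV (empty area = missing)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"modifications": "string"})
    _check_columns(df, AREA_COLUMNS, f"area table {path}")
    return df


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, META_COLUMNS, f"sample metadata {path}")
    dup = df.duplicated(subset=["genotype", "treatment", "replicate"])
    if dup.any():
        raise SchemaError("duplicate (genotype, treatment, replicate) in metadata")
    return df
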