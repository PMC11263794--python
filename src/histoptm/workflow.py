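"""Configuration-driven orchestration of the full pipeline.

Stages run in the order map -> quantify -> compare -> compensate ->
localize, writing tidy TSVs plus a JSON manifest (config hash, seed,
per-stage row counts, stage status). Re-running with identical inputs and
seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import compensation, compstats, localization, peptide_map, quantify
from .errors import ConfigError, HistoptmError

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "alpha": 0.05,
    "delta": 0.65,
    "grouping": "genotype",
    "max_missed": 2,
    "reference": "WT",
    "seed": 0,
    "counts": None,
    "ratios": None,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    fasta: str
    areas: str
    meta: str
    out_dir: str
    counts: Optional[str] = None
    grouping: str = "genotype"
    alpha: float = 0.05
    delta: float = 0.65
    max_missed: int = 2
    reference: str = "WT"
    seed: int = 0
    ratios: Optional[dict] = None  # genotype -> H3.1:H3.3 ratio override


def validate_config(raw: dict) -> RunConfig:
    """Normalize a parsed config document, filling and logging defaults.

    Unknown keys are rejected rather than silently ignored.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    required = {"fasta", "areas", "meta", "out_dir"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"missing required config key(s): {', '.join(sorted(missing))}")
    merged = dict(raw)
    for key, default in _DEFAULTS.items():
        if key not in merged:
            merged[key] = default
            logger.info("config: defaulted %s = %r", key, default)
    if not (0.0 < merged["alpha"] < 1.0):
        raise ConfigError(f"alpha={merged['alpha']} outside (0, 1)")
    if not (0.0 < merged["delta"] <= 1.0):
        raise ConfigError(f"delta={merged['delta']} outside (0, 1]")
    if merged["grouping"] not in ("genotype", "treatment"):
        raise ConfigError("grouping must be 'genotype' or 'treatment'")
    for key in ("fasta", "areas", "meta"):
        if not Path(merged[key]).exists():
            raise ConfigError(f"config path {key} does not exist: {merged[key]}")
    return RunConfig(**merged)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _compare_forms(
    forms: pd.DataFrame, meta: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Per-form log-ratio comparisons across the grouping variable.

    Within the genotype design the four genotypes (control arm) are compared
    by ANOVA + Tukey HSD; within the treatment design each genotype's
    control and zeocin arms are compared by Student t tests. All tests run
    on alr2-log2 values of imputed compositions.
    """
    merged = forms.merge(meta, on="sample_id")
    rows = []
    for region, sub in merged.groupby("region"):
        wide = sub.pivot_table(
            index="sample_id", columns="form_id", values="percent", dropna=False
        )
        sub_meta = meta.set_index("sample_id").loc[wide.index]
        if config.grouping == "genotype":
            sel = sub_meta["treatment"] == "control"
            wide_g, groups_lab = wide[sel.values], sub_meta.loc[sel.values, "genotype"]
        else:
            wide_g, groups_lab = wide, sub_meta["genotype"] + "." + sub_meta["treatment"]
        if wide_g.empty:
            continue
        imputed, _ = compstats.impute_missing(wide_g, groups_lab, config.delta)
        if imputed.shape[1] < 2:
            continue  # single-form region: no within-region log-ratio to test
        for form in imputed.columns:
            logratio = compstats.alr2_log2(imputed[form].values)
            series = pd.Series(logratio, index=imputed.index)
            if config.grouping == "genotype":
                groups = {
                    g: series[groups_lab == g].values
                    for g in groups_lab.unique()
                    if (groups_lab == g).sum() >= 2
                }
                if len(groups) < 2:
                    continue
                omnibus, pairwise, letters = compstats.anova_tukey(
                    groups, alpha=config.alpha, quantity=f"{region} {form}"
                )
                rows.append(
                    {
                        "quantity": f"{region} {form}",
                        "comparison": "one-way ANOVA",
                        "statistic": omnibus.statistic,
                        "df": str(omnibus.df),
                        "p": omnibus.p,
                        "adjusted_p": "",
                        "letters": json.dumps(letters, sort_keys=True),
                    }
                )
                for res in pairwise:
                    rows.append(
                        {
                            "quantity": res.quantity,
                            "comparison": res.comparison,
                            "statistic": res.statistic,
                            "df": str(res.df),
                            "p": res.p,
                            "adjusted_p": res.adjusted_p,
                            "letters": "",
                        }
                    )
            else:
                for genotype in sub_meta["genotype"].unique():
                    a = series[(sub_meta["genotype"] == genotype) & (sub_meta["treatment"] == "control")]
                    b = series[(sub_meta["genotype"] == genotype) & (sub_meta["treatment"] == "zeocin")]
                    if len(a) < 2 or len(b) < 2:
                        continue
                    res = compstats.two_condition_ttest(
                        a.values, b.values, quantity=f"{region} {form}"
                    )
                    rows.append(
                        {
                            "quantity": res.quantity,
                            "comparison": f"{genotype}: control vs zeocin",
                            "statistic": res.statistic,
                            "df": str(res.df),
                            "p": res.p,
                            "adjusted_p": "",
                            "letters": "",
                        }
                    )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("histoptm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def finish(stage: str, n_rows: int) -> None:
        manifest["stages"][stage] = {"status": "PASSED", "rows": n_rows}

    current = "map"
    try:
        db = peptide_map.read_fasta(config.fasta)
        pmap, groups, _ = peptide_map.build_peptide_map(db, config.max_missed)
        pmap.to_csv(out / "peptide_map.tsv", sep="\t", index=False)
        finish("map", len(pmap))

        current = "quantify"
        areas = quantify.read_area_table(config.areas)
        meta = quantify.read_sample_meta(config.meta)
        collapsed = quantify.collapse_charge_states(areas)
        forms = quantify.form_relative_abundance(collapsed, pmap)
        forms.to_csv(out / "form_compositions.tsv", sep="\t", index=False)
        family_of_group = {g.display_name: g.family.value for g in groups}
        prop_tables = []
        for family in sorted({f for f in family_of_group.values() if f != "other"}):
            n_variants = sum(
                1 for g in groups
                if g.family.value == family and g.has_unique_evidence
            )
            if n_variants < 2:
                continue
            prop_tables.append(
                quantify.variant_proportions(collapsed, pmap, family_of_group, family)
            )
        props = pd.concat(prop_tables, ignore_index=True) if prop_tables else pd.DataFrame()
        props.to_csv(out / "variant_proportions.tsv", sep="\t", index=False)

        h3 = props[props["family"] == "H3"] if not props.empty else pd.DataFrame()
        mixtures = {}
        if not h3.empty:
            ratios = quantify.variant_pair_ratio(h3, "H3.1", "H3.3", meta)
            ratios.to_csv(out / "h3_ratios.tsv", sep="\t", index=False)
            for _, row in ratios.iterrows():
                mixtures[row["sample_id"]] = compensation.mixture_from_ratio(row["ratio"])
            marks = quantify.mark_table(forms, mixtures)
            marks.to_csv(out / "mark_abundances.tsv", sep="\t", index=False)
        finish("quantify", len(forms))

        current = "compare"
        tests = _compare_forms(forms, meta, config)
        tests.to_csv(out / "tests.tsv", sep="\t", index=False)
        finish("compare", len(tests))

        current = "compensate"
        comp_rows = []
        if not h3.empty:
            merged = forms.merge(meta, on="sample_id")
            h3_forms = merged[merged["variant"].isin(["H3.1", "H3.3"])]

            def mean_profile(genotype, variant):
                block = h3_forms[
                    (h3_forms["genotype"] == genotype)
                    & (h3_forms["treatment"] == "control")
                    & (h3_forms["variant"] == variant)
                ]
                wide = block.pivot_table(index="sample_id", columns="form_id", values="percent")
                imputed, _ = compstats.impute_missing(
                    wide, pd.Series("all", index=wide.index), config.delta
                )
                prof = imputed.mean(axis=0)
                return dict(100.0 * prof / prof.sum())

            wt31 = mean_profile(config.reference, "H3.1")
            wt33 = mean_profile(config.reference, "H3.3")
            ratio_by_geno = (
                quantify.variant_pair_ratio(h3, "H3.1", "H3.3", meta)
                .groupby("genotype")["ratio"].mean()
            )
            for genotype in meta["genotype"].unique():
                if genotype == config.reference:
                    continue
                r = (config.ratios or {}).get(genotype, ratio_by_geno.get(genotype))
                if r is None or not np.isfinite(r):
                    continue
                mixture = compensation.mixture_from_ratio(float(r))
                expected = compensation.expected_mark_abundance(wt31, wt33, mixture)
                mut31 = mean_profile(genotype, "H3.1")
                mut33 = mean_profile(genotype, "H3.3")
                found = {}
                for mark, pct in mut31.items():
                    found[("H3.1", mark)] = mixture.f_h31 * pct
                for mark, pct in mut33.items():
                    found[("H3.3", mark)] = mixture.f_h33 * pct
                table = compensation.compensation_delta(expected, found)
                table.insert(0, "genotype", genotype)
                comp_rows.append(table)
        comp = pd.concat(comp_rows, ignore_index=True) if comp_rows else pd.DataFrame()
        comp.to_csv(out / "compensation.tsv", sep="\t", index=False)
        finish("compensate", len(comp))

        current = "localize"
        if config.counts:
            counts = pd.read_csv(config.counts)
            loc = localization.localization_tests(counts, reference=config.reference)
            loc.to_csv(out / "localization_tests.tsv", sep="\t", index=False)
            finish("localize", len(loc))
        else:
            manifest["stages"]["localize"] = {"status": "SKIPPED", "rows": 0}
    except HistoptmError as exc:
        manifest["stages"][current] = {"status": "FAILED", "error": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
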