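"""Synthetic peak-area and nuclei-count generator emulating the study design.

The generator produces the same long-format tables the quantification stage
consumes: 4 genotypes (WT, fas1, fas1_m123_2, m123_2) x 2 treatments
(control, zeocin) x 6 biological replicates, with per-peptidoform lognormal
peak-area noise, optional missing values, and genotype-specific variant
mixtures and modification profiles. Ground truth is emitted alongside every
dataset so estimator recovery can be checked.

The shipped protein database is synthetic: the two H3 K27-R40 peptides
(KSAPATGGVKKPHR / KSAPTTGGVKKPHR, distinguishable by the Ala/Thr replacement
at position 31) are embedded at mature positions 27-40 behind the conserved
H3 N-terminal residues, and the H2A.Z / H2A.W / H4 entries are engineered
sequences that reproduce the unique-peptide structure needed for variant
quantification — including a truncated H2A.W entry with no unique peptide,
which grouping must exclude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidDataError
from .quantify import UNMODIFIED, GENOTYPES, TREATMENTS

# --- synthetic histone database -------------------------------------------

_H3_NTERM = "ARTKQTARKSTGGKAPRKQLATKAAR"  # conserved residues 1-26
_H3_TAIL = "YRPGTVALR"
_Z_COMMON1 = "AGGKAGKDSGKAKAKAVSR"
_Z_COMMON2 = "HLQLAIRGDEELDSLIK"
_W_COMMON2 = "HIGLAVKNDEELGKLLAGVTIAHGGVLPNINPELLAKK"

#: mature sequences of the synthetic database, keyed by display name
SYNTHETIC_PROTEINS: dict[str, tuple[str, str]] = {
    # display -> (family, mature sequence)
    "H3.1": ("H3", _H3_NTERM + "KSAPATGGVKKPHR" + _H3_TAIL),
    "H3.3": ("H3", _H3_NTERM + "KSAPTTGGVKKPHR" + _H3_TAIL),
    "H2A.Z.9": ("H2A.Z", _Z_COMMON1 + "DEELNKLLGNVTIAQGGVLPNIQAVR" + _Z_COMMON2),
    "H2A.Z.8": ("H2A.Z", _Z_COMMON1 + "DEELNKLLGSVTIAQGGVLPNIQSVR" + _Z_COMMON2),
    "H2A.Z.11": ("H2A.Z", _Z_COMMON1 + "DEELNKLLGKVTIAQGGVLPNIQTVR" + _Z_COMMON2),
    "H2A.W.6": ("H2A.W", "ESSGATPKKAGR" + "VGAGAPVYLAAVLEYLAAEVLELAGNAAR" + _W_COMMON2),
    "H2A.W.7": ("H2A.W", "ESSGATPKKAGR" + "VGSGAPVYLAAVLEYLAAEVLELAGNASR" + _W_COMMON2),
    # truncated entry sharing every observable peptide with W.6/W.7
    "H2A.W.12": ("H2A.W", _W_COMMON2),
    "H4": ("H4", "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIR"),
}

#: the region peptide quantified for each variant (its unique peptide,
#: except H4 where the single entry is trivially unique)
VARIANT_REGION_PEPTIDE: dict[str, str] = {
    "H3.1": "KSAPATGGVKKPHR",
    "H3.3": "KSAPTTGGVKKPHR",
    "H2A.Z.9": "DEELNKLLGNVTIAQGGVLPNIQAVR",
    "H2A.Z.8": "DEELNKLLGSVTIAQGGVLPNIQSVR",
    "H2A.Z.11": "DEELNKLLGKVTIAQGGVLPNIQTVR",
    "H2A.W.6": "VGAGAPVYLAAVLEYLAAEVLELAGNAAR",
    "H2A.W.7": "VGSGAPVYLAAVLEYLAAEVLELAGNASR",
    "H4": "GKGGKGLGKGGAKR",
}

VARIANT_FAMILY: dict[str, str] = {
    "H3.1": "H3",
    "H3.3": "H3",
    "H2A.Z.9": "H2A.Z",
    "H2A.Z.8": "H2A.Z",
    "H2A.Z.11": "H2A.Z",
    "H2A.W.6": "H2A.W",
    "H2A.W.7": "H2A.W",
    "H4": "H4",
}


def write_synthetic_fasta(path: str | Path) -> Path:
    """Write the synthetic histone database as FASTA (raw sequences carry
    an initiator Met so numbering exercises Met stripping)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (name, (family, mature)) in enumerate(SYNTHETIC_PROTEINS.items(), 1):
            fh.write(f">SYN{i:03d} {name} family={family} synthetic\n")
            fh.write("M" + mature + "\n")
    return path


# --- generator configuration ----------------------------------------------


@dataclass
class GenotypeTruth:
    """Ground-truth variant mixtures and within-variant form profiles."""

    mixtures: dict[str, dict[str, float]]  # family -> variant -> percent
    profiles: dict[str, dict[str, float]]  # variant -> form -> percent


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    noise_cv is the lognormal coefficient of variation of peak areas;
    treatment effects are additive shifts of single forms on the alr2-log2
    scale. With censor_quantile > 0 the lowest areas of each sample are
    censored instead of (or in addition to) missing completely at random.
    """

    genotypes: dict[str, GenotypeTruth]
    treatments: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {"control": {}}
    )
    n_replicates: int = 6
    noise_cv: float = 0.2
    missing_rate: float = 0.0
    area_scale: float = 1e7
    censor_quantile: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.noise_cv < 0 or self.area_scale <= 0:
            raise ConfigError("noise_cv must be >= 0 and area_scale > 0")
        for g, truth in self.genotypes.items():
            for fam, mix in truth.mixtures.items():
                if abs(sum(mix.values()) - 100.0) > 1e-6:
                    raise ConfigError(f"{g}/{fam} mixture does not close to 100")
            for v, prof in truth.profiles.items():
                if abs(sum(prof.values()) - 100.0) > 1e-6:
                    raise ConfigError(f"{g}/{v} profile does not close to 100")


def close(parts: Mapping[str, float]) -> dict[str, float]:
    """Rescale a part map to sum to 100."""
    total = sum(parts.values())
    if total <= 0:
        raise InvalidDataError("cannot close non-positive parts")
    return {k: 100.0 * v / total for k, v in parts.items()}


def apply_alr2_shifts(
    profile: Mapping[str, float], shifts: Mapping[str, float]
) -> dict[str, float]:
    """Shift selected forms on the alr2-log2 scale (sequentially, in sorted
    form order), holding the remaining forms proportional."""
    prof = dict(profile)
    for form in sorted(shifts):
        if form not in prof:
            continue
        p = prof[form]
        odds = p / (100.0 - p) * 2.0 ** shifts[form]
        p_new = 100.0 * odds / (1.0 + odds)
        scale = (100.0 - p_new) / (100.0 - p)
        for other in prof:
            prof[other] = prof[other] * scale if other != form else p_new
    return prof


# --- presets ---------------------------------------------------------------

_H31_PROFILE = {
    UNMODIFIED: 5.0,
    "K27me1": 55.0,
    "K27me2": 25.0,
    "K27me3": 10.0,
    "K36me1": 3.0,
    "K36me2": 2.0,
}
_H33_PROFILE_WT = {
    UNMODIFIED: 29.0,
    "K27me1": 30.0,
    "K27me2": 12.0,
    "K27me3": 6.0,
    "K36me1": 13.0,
    "K36me2": 10.0,
}
_H33_PROFILE_FAS1 = {
    UNMODIFIED: 35.0,
    "K27me1": 36.0,
    "K27me2": 10.0,
    "K27me3": 5.0,
    "K36me1": 8.0,
    "K36me2": 6.0,
}
_H33_PROFILE_FAS1_M123 = {
    UNMODIFIED: 32.0,
    "K27me1": 33.0,
    "K27me2": 11.0,
    "K27me3": 5.5,
    "K36me1": 10.5,
    "K36me2": 8.0,
}
_Z_PROFILE = {UNMODIFIED: 85.0, "K25ac": 15.0}
_W_PROFILE = {UNMODIFIED: 100.0}
_H4_PROFILE = {
    UNMODIFIED: 50.0,
    "K8ac": 20.0,
    "K12ac": 15.0,
    "K16ac": 10.0,
    "K8ac;K16ac": 5.0,
}

#: WT H2A.Z proportions reported for the study system (closed to 100)
WT_H2AZ_TRUTH = close({"H2A.Z.9": 67.0, "H2A.Z.8": 7.0, "H2A.Z.11": 25.0})

#: H3.1:H3.3 ratios reported for WT and fas1
WT_H3_RATIO = 3.0
FAS1_H3_RATIO = 0.8


def _h3_mixture(ratio: float) -> dict[str, float]:
    return {
        "H3.1": 100.0 * ratio / (1.0 + ratio),
        "H3.3": 100.0 / (1.0 + ratio),
    }


def preset_study(
    seed: int = 0,
    noise_cv: float = 0.2,
    missing_rate: float = 0.02,
    n_replicates: int = 6,
) -> GeneratorConfig:
    """The full study design: 4 genotypes x 2 treatments x 6 replicates.

    Variant-mixture ground truths encode the reported profiles: WT H2A.Z
    split ~67/7/25, H3.1:H3.3 ratios 3:1 (WT) and ~0.8:1 (fas1), H2A.W.7
    gain in fas1, and a zeocin effect raising H3.3 K27me1 while lowering
    K36 methylation.
    """

    def truth(h3_ratio, h2az, h2aw, h33_profile):
        return GenotypeTruth(
            mixtures={
                "H3": _h3_mixture(h3_ratio),
                "H2A.Z": close(h2az),
                "H2A.W": close(h2aw),
                "H4": {"H4": 100.0},
            },
            profiles={
                "H3.1": dict(_H31_PROFILE),
                "H3.3": dict(h33_profile),
                "H2A.Z.9": dict(_Z_PROFILE),
                "H2A.Z.8": dict(_Z_PROFILE),
                "H2A.Z.11": dict(_Z_PROFILE),
                "H2A.W.6": dict(_W_PROFILE),
                "H2A.W.7": dict(_W_PROFILE),
                "H4": dict(_H4_PROFILE),
            },
        )

    genotypes = {
        "WT": truth(WT_H3_RATIO, WT_H2AZ_TRUTH, {"H2A.W.6": 80, "H2A.W.7": 20}, _H33_PROFILE_WT),
        "fas1": truth(FAS1_H3_RATIO, {"H2A.Z.9": 68, "H2A.Z.8": 5, "H2A.Z.11": 27},
                      {"H2A.W.6": 55, "H2A.W.7": 45}, _H33_PROFILE_FAS1),
        "fas1_m123_2": truth(1.5, {"H2A.Z.9": 64, "H2A.Z.8": 6, "H2A.Z.11": 30},
                             {"H2A.W.6": 68, "H2A.W.7": 32}, _H33_PROFILE_FAS1_M123),
        "m123_2": truth(WT_H3_RATIO, {"H2A.Z.9": 60, "H2A.Z.8": 7, "H2A.Z.11": 33},
                        {"H2A.W.6": 80, "H2A.W.7": 20}, _H33_PROFILE_WT),
    }
    treatments = {
        "control": {},
        "zeocin": {
            ("H3.3", "K27me1"): 0.6,
            ("H3.3", "K36me1"): -0.5,
            ("H3.3", "K36me2"): -0.5,
            ("H4", "K16ac"): 0.3,
        },
    }
    return GeneratorConfig(
        genotypes=genotypes,
        treatments=treatments,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
        missing_rate=missing_rate,
        seed=seed,
    )


def preset_null(seed: int = 0, noise_cv: float = 0.2, n_replicates: int = 6) -> GeneratorConfig:
    """Two genotypes with identical ground truth (null for calibration)."""
    cfg = preset_study(seed=seed, noise_cv=noise_cv, missing_rate=0.0,
                       n_replicates=n_replicates)
    wt = cfg.genotypes["WT"]
    return replace(
        cfg,
        genotypes={"WT": wt, "fas1": GenotypeTruth(
            mixtures={f: dict(m) for f, m in wt.mixtures.items()},
            profiles={v: dict(p) for v, p in wt.profiles.items()},
        )},
        treatments={"control": {}},
    )


# --- generation ------------------------------------------------------------

_CHARGE_SPLIT = ((2, 0.7), (3, 0.3))


def gen_peak_areas(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (peak-area table, sample metadata, ground truth).

    Per sample, each peptidoform's total area is
    area_scale x variant fraction x form fraction x lognormal(1, noise_cv),
    split deterministically over two charge states; cells then go missing
    independently with probability missing_rate (and/or by low-area
    censoring when censor_quantile > 0). Fully deterministic under the
    config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2)))

    area_rows = []
    meta_rows = []
    truth: dict = {"mixtures": {}, "profiles": {}, "config": {
        "n_replicates": config.n_replicates, "noise_cv": config.noise_cv,
        "missing_rate": config.missing_rate, "seed": config.seed,
    }}
    for genotype, g_truth in config.genotypes.items():
        truth["mixtures"][genotype] = g_truth.mixtures
        for treatment, shifts in config.treatments.items():
            eff_profiles = {}
            for variant, profile in g_truth.profiles.items():
                form_shifts = {f: s for (v, f), s in shifts.items() if v == variant}
                eff_profiles[variant] = apply_alr2_shifts(profile, form_shifts)
            truth["profiles"][f"{genotype}.{treatment}"] = eff_profiles

            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{genotype}.{treatment}.r{rep}"
                meta_rows.append(
                    {"sample_id": sample_id, "genotype": genotype,
                     "treatment": treatment, "replicate": rep}
                )
                for family, mixture in g_truth.mixtures.items():
                    for variant, pct in mixture.items():
                        frac = pct / 100.0
                        seq = VARIANT_REGION_PEPTIDE[variant]
                        for form, form_pct in eff_profiles[variant].items():
                            mean_area = config.area_scale * frac * form_pct / 100.0
                            noise = (
                                1.0 if config.noise_cv == 0
                                else float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
                            )
                            total = mean_area * noise
                            for charge, share in _CHARGE_SPLIT:
                                area_rows.append(
                                    {
                                        "sample_id": sample_id,
                                        "peptide_sequence": seq,
                                        "modifications": "" if form == UNMODIFIED else form,
                                        "charge": charge,
                                        "area": total * share,
                                    }
                                )

    areas = pd.DataFrame(area_rows)
    if config.missing_rate > 0:
        mask = rng.random(len(areas)) < config.missing_rate
        areas.loc[mask, "area"] = np.nan
    if config.censor_quantile > 0:
        threshold = areas.groupby("sample_id")["area"].transform(
            lambda s: s.quantile(config.censor_quantile)
        )
        areas.loc[areas["area"] < threshold, "area"] = np.nan
    meta = pd.DataFrame(meta_rows)
    return areas, meta, truth


def gen_nuclei_counts(
    p_true: float, n: int, seed: int, genotype: str = "", category: str = ""
) -> int:
    """Binomial draw of a nuclei category count; deterministic under seed."""
    if not (0.0 <= p_true <= 1.0):
        raise InvalidDataError("p_true must lie in [0, 1]")
    if n < 1:
        raise InvalidDataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n, p_true))


def gen_nuclei_table(
    truths: Mapping[str, Mapping[str, float]],
    n_per_genotype: Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Nuclei-count table for several genotypes and categories."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, cats in truths.items():
        n = n_per_genotype[genotype]
        for category, p in cats.items():
            rows.append(
                {
                    "genotype": genotype,
                    "category": category,
                    "count": int(rng.binomial(n, p)),
                    "n_total": n,
                }
            )
    return pd.DataFrame(rows)


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write areas (TSV), metadata (CSV), FASTA and ground truth (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    areas, meta, truth = gen_peak_areas(config)
    paths = {
        "areas": out / "areas.tsv",
        "meta": out / "samples.csv",
        "fasta": out / "synthetic_histones.fasta",
        "truth": out / "ground_truth.json",
    }
    areas.to_csv(paths["areas"], sep="\t", index=False)
    meta.to_csv(paths["meta"], index=False)
    write_synthetic_fasta(paths["fasta"])
    with open(paths["truth"], "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
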