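"""Readers, validation and end-to-end orchestration.

The single interchange format is a tidy long CSV with columns
``genotype, environment, replicate, trait, value`` — one observation per
plant and trait.  The full pipeline goes raw measurements -> derived
traits -> variance components -> heritability / BLUPs / correlations and
writes summary tables mirroring the usual multi-environment-trial report:
per-trait means, BLUP ranges, component significance and heritability, and
per-pair phenotypic / genotypic / environmental correlations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import quantgen, varcomp
from .varcomp import DesignInfo, validate_balance

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_phenotype_table",
    "write_phenotype_table",
    "wide_to_long",
    "map_environments",
    "run_full_pipeline",
]

log = logging.getLogger("wuequant")

REQUIRED_COLS = ["genotype", "environment", "replicate", "trait", "value"]


@dataclass
class RunConfig:
    """Switches and paths for one pipeline run."""

    phenotypes: str | Path | None = None   # tidy CSV; or provide a DataFrame to run_full_pipeline
    out_dir: str | Path = "results"
    traits: list[str] | None = None        # default: all traits in the table
    pairs: list[tuple[str, str]] | None = None  # default: all trait pairs
    correlation_basis: str = "individual"  # or "genotype-mean"
    lrt_reference: str = "mixture"         # or "naive"
    init: str = "moment"                   # REML start values
    seed: int = 0
    verbose: bool = False


@dataclass
class PipelineResult:
    summary: pd.DataFrame        # per-trait report
    components: pd.DataFrame     # per trait x stratum estimates
    correlations: pd.DataFrame   # per-pair correlation partition
    blups: dict[str, pd.Series]
    design: DesignInfo
    run_log: dict


# ---------------------------------------------------------------------------
# readers / writers

def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy phenotype CSV.

    Duplicate (genotype, environment, replicate, trait) keys and
    non-numeric values are rejected with their line numbers; missing
    values (empty or NA) are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[REQUIRED_COLS].copy()
    df.index = df.index + 2  # header is line 1

    key_cols = REQUIRED_COLS[:4]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        lines = df.index[dup].tolist()
        raise ValueError(
            f"{path}: duplicate (genotype, environment, replicate, trait) "
            f"keys at lines {lines[:10]}")

    raw = df["value"].str.strip()
    na_mask = raw.isin(["", "NA", "NaN", "nan", "na"])
    values = pd.to_numeric(raw.where(~na_mask), errors="coerce")
    bad = values.isna() & ~na_mask
    if bad.any():
        lines = df.index[bad].tolist()
        raise ValueError(
            f"{path}: non-numeric value(s) at lines {lines[:10]}")
    if na_mask.any():
        log.warning("%s: dropped %d missing value(s); design may be "
                    "unbalanced", path, int(na_mask.sum()))
    out = df.loc[~na_mask].copy()
    out["value"] = values[~na_mask].astype(float)
    if not np.isfinite(out["value"]).all():
        raise ValueError(f"{path}: non-finite values present")
    return out.reset_index(drop=True)


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table[REQUIRED_COLS].to_csv(path, index=False)


def wide_to_long(wide: pd.DataFrame,
                 id_cols=("genotype", "environment", "replicate")) -> pd.DataFrame:
    """Convenience converter from one-column-per-trait to the tidy layout."""
    return wide.melt(id_vars=list(id_cols), var_name="trait",
                     value_name="value").dropna(subset=["value"])


def map_environments(table: pd.DataFrame,
                     mapping: dict[tuple[str, str], str],
                     cols=("experiment", "treatment")) -> pd.DataFrame:
    """Collapse experiment x treatment labels into a single environment id."""
    out = table.copy()
    keys = list(zip(out[cols[0]], out[cols[1]]))
    unknown = {k for k in keys if k not in mapping}
    if unknown:
        raise ValueError(f"no environment mapping for {sorted(unknown)[:5]}")
    out["environment"] = [mapping[k] for k in keys]
    return out.drop(columns=list(cols))


# ---------------------------------------------------------------------------
# orchestration

def _sig_flag(p: float, threshold: float = 0.01) -> str:
    return f"<{threshold:g}" if p < threshold else "ns"


def _wald_environment_p(vc: varcomp.VarianceComponents) -> float:
    """Wald chi-square test that all environment means are equal (fixed part)."""
    fit = vc.fit
    if fit is None or fit.beta.size < 2:
        return np.nan
    t = fit.beta.size
    C = np.zeros((t - 1, t))
    C[:, 0] = 1.0
    C[np.arange(t - 1), np.arange(1, t)] = -1.0
    d = C @ fit.beta
    cov = C @ fit.beta_cov @ C.T
    try:
        w = float(d @ np.linalg.solve(cov, d))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(w, df=t - 1))


def run_full_pipeline(config: RunConfig,
                      table: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis and write the result bundle to ``out_dir``.

    Writes ``components.csv``, ``summary.csv`` (per-trait means, BLUP
    range, component p-values and heritability), ``correlations.csv`` and
    ``run_log.json``.  Any stage failure aborts with the stage name;
    files written before the failure are left in place.
    """
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name):
        def mark(**info):
            entry = {"stage": name, "elapsed_s": round(time.time() - t_start, 3),
                     **info}
            stages.append(entry)
            log.info("%s", entry)
        return mark

    if table is None:
        if config.phenotypes is None:
            raise ValueError("RunConfig.phenotypes or an in-memory table is required")
        table = read_phenotype_table(config.phenotypes)
        digest = hashlib.md5(
            Path(config.phenotypes).read_bytes()).hexdigest()
    else:
        digest = hashlib.md5(
            pd.util.hash_pandas_object(table).values.tobytes()).hexdigest()
    stage("read")(rows=len(table), input_md5=digest)

    traits = config.traits or sorted(table["trait"].unique())
    design = validate_balance(table, traits[0])

    comp_rows, summary_rows, blups = [], [], {}
    try:
        for trait in traits:
            d = validate_balance(table, trait)
            vc = varcomp.fit_reml_univariate(table, trait, init=config.init)
            lrt_g = varcomp.component_lrt(table, trait, "genotype",
                                           init=config.init)
            lrt_ge = varcomp.component_lrt(table, trait, "gxe",
                                            init=config.init)
            p_attr = ("p_mixture" if config.lrt_reference == "mixture"
                      else "p_naive")
            p_g = getattr(lrt_g, p_attr)
            p_ge = getattr(lrt_ge, p_attr)
            p_env = _wald_environment_p(vc)
            h2 = quantgen.heritability_mean_basis(vc, d.t, d.r)
            sub = table[table["trait"] == trait]
            if d.balanced:
                bt = quantgen.blup_genotype_means(table, vc, d)
                blup_lo, blup_hi = bt.blups.min(), bt.blups.max()
                blups[trait] = bt.blups
            else:
                fit_blup = vc.fit.blup["genotype"][:, 0]
                means = fit_blup + sub["value"].mean()
                blup_lo, blup_hi = float(np.min(means)), float(np.max(means))
            ses = np.sqrt(np.clip(np.diag(vc.asy_cov), 0.0, None))
            for i, (stratum, est) in enumerate(zip(
                    ("genotype", "gxe", "residual"), vc.as_array())):
                comp_rows.append({
                    "trait": trait, "stratum": stratum, "estimate": est,
                    "se": ses[i],
                    "constrained_flag": stratum in vc.boundary,
                })
            summary_rows.append({
                "trait": trait,
                "mean": sub["value"].mean(),
                "blup_min": blup_lo, "blup_max": blup_hi,
                "p_genotype": p_g, "p_environment": p_env, "p_gxe": p_ge,
                "sig_genotype": _sig_flag(p_g),
                "sig_environment": _sig_flag(p_env) if np.isfinite(p_env) else "-",
                "sig_gxe": _sig_flag(p_ge),
                "h2": h2.h2, "h2_se": h2.se,
            })
        stage("varcomp")(traits=len(traits))

        pairs = config.pairs or list(combinations(traits, 2))
        corr_rows = []
        for t1, t2 in pairs:
            cc = varcomp.fit_reml_bivariate(table, t1, t2, init=config.init)
            ce = quantgen.correlations_from_components(
                cc, design.t, design.r, basis=config.correlation_basis)
            corr_rows.append({
                "trait1": t1, "trait2": t2,
                "r_p": ce.r_p, "se_p": ce.se_p,
                "r_g": ce.r_g, "se_g": ce.se_g,
                "r_e": ce.r_e, "se_e": ce.se_e,
                "basis": ce.basis,
                "flags": ";".join(ce.flags),
            })
        stage("correlations")(pairs=len(pairs))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage failed after {stages[-1]['stage']}: {exc}"
        ) from exc

    summary = pd.DataFrame(summary_rows)
    components = pd.DataFrame(comp_rows)
    correlations = pd.DataFrame(corr_rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    components.to_csv(out_dir / "components.csv", index=False)
    correlations.to_csv(out_dir / "correlations.csv", index=False)

    from . import __version__
    run_log = {
        "seed": config.seed,
        "switches": {
            "correlation_basis": config.correlation_basis,
            "lrt_reference": config.lrt_reference,
            "init": config.init,
        },
        "design": {"g": design.g, "t": design.t, "r": design.r,
                   "balanced": design.balanced},
        "versions": {"wuequant": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": stages,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    stage("write")(out_dir=str(out_dir))
    return PipelineResult(summary=summary, components=components,
                          correlations=correlations, blups=blups,
                          design=design, run_log=run_log)
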