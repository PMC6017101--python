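"""File formats, analysis configuration and the end-to-end pipeline.

Dose-effect tables are delimited text (comma or tab) with a header and
columns ``agent_id``, ``dose_mg_per_ml`` and exactly one of
``fraction_affected`` or ``percent_inhibition``.  The pipeline reads one
such table holding both single agents and the fixed-ratio mixture, fits
all three with the median-effect model, computes the CI profile and DRI
table, and writes a versioned JSON report plus flat CSV exports and the
Fa-CI figure.  Identical config and inputs give a byte-identical JSON
report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .combination import (
    DEFAULT_CI_BANDS,
    CombinationModel,
    classify_ci,
    compute_dri,
)
from .median_effect import (
    DEFAULT_USABILITY_BAND,
    DoseEffectSeries,
    MedianEffectModel,
)

__all__ = [
    "AnalysisConfig",
    "read_dose_effect",
    "write_dose_effect",
    "run_pipeline",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

logger = logging.getLogger("combindex")


def read_dose_effect(path) -> dict[str, DoseEffectSeries]:
    """Parse a dose-effect table into series keyed by agent.

    Exactly one of ``fraction_affected`` / ``percent_inhibition`` must be
    present; percent is converted to fraction.  Errors name the offending
    row (1-based, counting the header as row 1) and field.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = set(df.columns)
    if "agent_id" not in cols or "dose_mg_per_ml" not in cols:
        raise ValueError(f"{path}: need columns agent_id and dose_mg_per_ml, "
                         f"found {sorted(cols)}")
    has_fa, has_pct = "fraction_affected" in cols, "percent_inhibition" in cols
    if has_fa == has_pct:
        raise ValueError(f"{path}: need exactly one of fraction_affected or "
                         "percent_inhibition")
    eff_col = "fraction_affected" if has_fa else "percent_inhibition"

    for col in ("dose_mg_per_ml", eff_col):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[bad | vals.isna()]:
            raise ValueError(f"{path}: row {idx + 2}: non-numeric {col} "
                             f"({df.loc[idx, col]!r})")
        df[col] = vals
    for idx in df.index[df["dose_mg_per_ml"] <= 0]:
        raise ValueError(f"{path}: row {idx + 2}: dose_mg_per_ml must be > 0 "
                         f"({df.loc[idx, 'dose_mg_per_ml']!r})")
    fa = df[eff_col] / 100.0 if has_pct else df[eff_col]
    for idx in df.index[(fa < 0) | (fa > 1)]:
        raise ValueError(f"{path}: row {idx + 2}: {eff_col} out of range "
                         f"({df.loc[idx, eff_col]!r})")
    df = df.assign(fraction_affected=fa)

    return {
        str(aid): DoseEffectSeries(str(aid), grp["dose_mg_per_ml"].to_numpy(),
                                   grp["fraction_affected"].to_numpy())
        for aid, grp in df.groupby("agent_id", sort=False)
    }


def write_dose_effect(series: Sequence[DoseEffectSeries] | DoseEffectSeries, path) -> None:
    """Write one or more series as the standard dose-effect CSV."""
    if isinstance(series, DoseEffectSeries):
        series = [series]
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


class AnalysisConfig(BaseModel):
    """Declarative description of one combination analysis run."""

    model_config = ConfigDict(frozen=True)

    input_path: str
    agent1: str
    agent2: str
    mixture: str
    ratio: float | Literal["from-ic50s"] = "from-ic50s"
    duration_min: float | None = Field(
        default=None, description="kinetic window for the assay stage, if raw OD input")
    usability_band: tuple[float, float] = DEFAULT_USABILITY_BAND
    ci_bands: tuple[float, float] = DEFAULT_CI_BANDS
    effect_grid: tuple[float, float, int] = (0.01, 0.99, 99)
    dri_levels: tuple[float, ...] = (0.50, 0.75, 0.90, 0.95)
    output_dir: str = "."
    seed: int = 0
    verbose: bool = False

    def fa_grid(self) -> np.ndarray:
        lo, hi, n = self.effect_grid
        return np.linspace(lo, hi, int(n))


def run_pipeline(config: AnalysisConfig, make_figure: bool = True) -> dict:
    """Run fits -> CI profile -> DRI table -> report bundle.

    Returns the report dict and writes ``report.json``, ``fa_ci.csv``,
    ``dri.csv`` and (optionally) ``fa_ci.png`` under ``output_dir``.
    """
    level = logging.DEBUG if config.verbose else logging.INFO
    logging.basicConfig(level=level, format="%(name)s %(levelname)s %(message)s")

    collection = read_dose_effect(config.input_path)
    for name in (config.agent1, config.agent2, config.mixture):
        if name not in collection:
            raise ValueError(
                f"input {config.input_path}: required agent_id {name!r} not found "
                f"(available: {sorted(collection)})")

    fits = {}
    for name in (config.agent1, config.agent2):
        model = MedianEffectModel.from_series(collection[name],
                                              usability_band=config.usability_band)
        fits[name] = model.fit()
        logger.info("fit %s: Dm=%.4g m=%.4g r=%.4f n=%d", name, fits[name].dm,
                    fits[name].m, fits[name].r, fits[name].n_used)
        for i, d, fa, why in fits[name].excluded:
            logger.debug("fit %s: excluded point %d (D=%g, fa=%g): %s",
                         name, i, d, fa, why)

    ratio = (fits[config.agent1].dm / (fits[config.agent1].dm + fits[config.agent2].dm)
             if config.ratio == "from-ic50s" else float(config.ratio))
    combo = CombinationModel(collection[config.mixture], ratio,
                             usability_band=config.usability_band).fit()
    logger.info("mixture %s: Dm=%.4g ratio=%.4f", config.mixture, combo.dm, ratio)

    profile = combo.ci_profile(fits[config.agent1], fits[config.agent2],
                               fa_grid=config.fa_grid(), bands=config.ci_bands)
    dri = compute_dri(combo, fits[config.agent1], fits[config.agent2],
                      levels=config.dri_levels)
    overall = classify_ci(float(np.median(profile.ci)), bands=config.ci_bands)
    logger.info("CI median over grid: %.3f -> %s", float(np.median(profile.ci)), overall)

    # analysis parameters only: where the bundle is written and how chatty
    # the log is are run-environment concerns, not part of the result
    config_out = json.loads(config.model_dump_json(exclude={"output_dir", "verbose"}))
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config_out,
        "fits": {name: f.to_dict() for name, f in fits.items()},
        "mixture_fit": combo.mixture.to_dict(),
        "ratio": ratio,
        "dm_split": list(combo.dm_split),
        "ci_profile": profile.table.drop(columns="classification").to_dict(orient="list"),
        "ci_classification": profile.table["classification"].tolist(),
        "dri": dri.table.to_dict(orient="list"),
        "overall_classification": overall,
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    profile.to_csv(out / "fa_ci.csv")
    dri.table.to_csv(out / "dri.csv", index=False)
    if make_figure:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = profile.plot()
        ax.figure.savefig(out / "fa_ci.png", dpi=150)
        plt.close(ax.figure)
    return report
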