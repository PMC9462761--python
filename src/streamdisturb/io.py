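"""Readers, writers, configuration and the end-to-end pipeline runner.

All tables are delimited text (comma by default, tab accepted), UTF-8,
with '.' as the decimal separator.  Site and species identifiers are
opaque strings.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import spearman_screen, trend_test
from .disturbance import ProximityWeights, score_sites
from .indval import IndicatorSpeciesAnalysis
from .metrics import diversity_table, restrictedness, validate_abundance
from .ordination import DistanceRDA, bray_curtis, select_variables
from .rhda import RHDAConfig, RHDASheet, score_rhda

__all__ = [
    "PipelineConfig",
    "read_abundance",
    "write_abundance",
    "read_site_table",
    "read_tallies",
    "read_species_attributes",
    "read_rhda_sheets",
    "read_delimited",
    "run_pipeline",
]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_delimited(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep_for(path), **kwargs)


def read_abundance(path) -> pd.DataFrame:
    """Read a site x species abundance matrix (rows = sites, header row of
    species ids); validates labels, integer counts and non-negativity."""
    df = read_delimited(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    try:
        return validate_abundance(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_abundance(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep=_sep_for(Path(path)))


def read_site_table(path) -> pd.DataFrame:
    """Read the per-site attribute table (land use, RHDA, water chemistry);
    requires a ``site_id`` column, which becomes the index."""
    df = read_delimited(path)
    if "site_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'site_id'")
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"{path}: duplicate site ids {dups}")
    return df.set_index("site_id")


def read_tallies(path) -> pd.DataFrame:
    """Read the long-format local-disturbance tally table
    (site_id, category, one column per transect)."""
    df = read_delimited(path, dtype=str)
    for col in ("site_id", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_species_attributes(path) -> pd.DataFrame:
    """Read the species-attribute table (species_id, basin, origin, endemic)."""
    df = read_delimited(path)
    required = {"species_id", "origin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = ~df["origin"].astype(str).str.upper().isin(["NATIVE", "NON_NATIVE"])
    if bad.any():
        raise ValueError(
            f"{path}: invalid origin values {df.loc[bad, 'origin'].unique().tolist()}"
        )
    df["origin"] = df["origin"].astype(str).str.upper()
    return df


def read_rhda_sheets(path) -> dict[str, list[RHDASheet]]:
    """Read RHDA sheets (site_id, observer_id, p01..p22) grouped by site."""
    df = read_delimited(path)
    pcols = [f"p{i:02d}" for i in range(1, 23)]
    missing = [c for c in ["site_id", *pcols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, list[RHDASheet]] = {}
    for _, row in df.iterrows():
        sheet = RHDASheet(
            scores=tuple(float(row[c]) for c in pcols),
            observer_id=str(row.get("observer_id", "")) or None,
        )
        out.setdefault(str(row["site_id"]), []).append(sheet)
    return out


@dataclass
class PipelineConfig:
    """File paths, thresholds and seeds for a full pipeline run.

    Thresholds default to the workflow's conventions: classification bounds
    (0.10, 0.20), Spearman cutoff 0.7, VIF cutoff 10, alpha 0.05 and 999
    permutations.
    """

    tallies: str | None = None
    landuse: str | None = None
    abundance: str | None = None
    species_attributes: str | None = None
    rhda_sheets: str | None = None
    env_columns: list[str] | None = None
    weights: ProximityWeights = field(default_factory=ProximityWeights)
    idi_variant: str = "printed"
    class_thresholds: tuple[float, float] = (0.10, 0.20)
    r_max: float = 0.7
    vif_max: float = 10.0
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "weights" in raw:
            raw["weights"] = ProximityWeights(**raw["weights"])
        if "class_thresholds" in raw:
            raw["class_thresholds"] = tuple(raw["class_thresholds"])
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload["weights"] = asdict(self.weights)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_ENV_DEFAULT_EXCLUDE = {"level", "ldi", "cdi", "idi_clamped"}


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full workflow and write all stage outputs to ``out_dir``.

    Stage order follows the analysis design: disturbance scoring and RHDA,
    the environmental correlation screen, then — when abundance data are
    present — dbRDA, indicator-species analysis, restrictedness, diversity
    profiles and trend tests.  Community stages are skipped, with a logged
    note, when no abundance matrix is configured.  A manifest (config hash,
    seed, package version, outputs) makes reruns verifiable: identical
    manifests imply identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped: list[str] = []

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        df.to_csv(out / name, float_format="%.6g", **kwargs)
        written.append(name)

    if config.landuse is None:
        raise ValueError("pipeline requires a land-use/site table")
    site_table = read_site_table(config.landuse)

    # -- disturbance scoring ------------------------------------------------
    stage = "disturbance"
    try:
        if config.tallies is not None:
            tallies = read_tallies(config.tallies)
            scores = score_sites(
                tallies,
                site_table.reset_index(),
                weights=config.weights,
                variant=config.idi_variant,
                thresholds=config.class_thresholds,
            )
        elif "idi" in site_table.columns:
            from .disturbance import classify_disturbance

            scores = pd.DataFrame(index=site_table.index)
            scores["idi"] = site_table["idi"]
            scores["level"] = [
                classify_disturbance(v, thresholds=config.class_thresholds).value
                for v in site_table["idi"]
            ]
        else:
            raise ValueError("need either a tally file or an 'idi' site column")
        save(scores, "disturbance_scores.csv")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- RHDA ---------------------------------------------------------------
    if config.rhda_sheets is not None:
        sheets = read_rhda_sheets(config.rhda_sheets)
        rows = [
            {"site_id": site,
             "rhda_total": score_rhda(shts).total,
             "n_observers": len(shts)}
            for site, shts in sorted(sheets.items())
        ]
        save(pd.DataFrame(rows).set_index("site_id"), "rhda_scores.csv")
    else:
        skipped.append("rhda: no sheet file configured")

    # -- correlation screen -------------------------------------------------
    env_cols = config.env_columns or [
        c
        for c in site_table.columns
        if c not in _ENV_DEFAULT_EXCLUDE
        and pd.api.types.is_numeric_dtype(site_table[c])
    ]
    env = site_table[env_cols].copy()
    if "idi" in scores.columns and "idi" not in env.columns:
        env["idi"] = scores["idi"]
    screen = spearman_screen(env, alpha=config.alpha)
    save(screen.to_long(), "correlation_screen.csv", index=False)

    # -- community stages ---------------------------------------------------
    if config.abundance is None:
        skipped.append("community stages: no abundance matrix configured")
    else:
        matrix = read_abundance(config.abundance)
        matrix = matrix.loc[[s for s in site_table.index if s in matrix.index]]
        attrs = (
            read_species_attributes(config.species_attributes)
            if config.species_attributes
            else None
        )

        selected, exclusions = select_variables(
            env.loc[matrix.index], r_max=config.r_max,
            vif_max=config.vif_max, alpha=config.alpha,
        )
        save(pd.DataFrame(exclusions,
                          columns=["variable", "stage", "reason"]),
             "variable_exclusions.csv", index=False)

        results = DistanceRDA.from_abundance(matrix, selected).fit()
        save(results.site_scores, "dbrda_site_scores.csv")
        save(results.biplot_scores, "dbrda_biplot_scores.csv")
        axis_tests = results.permutation_test(
            by="axis", n_perm=config.n_perm, seed=config.seed
        )
        margin_tests = results.permutation_test(
            by="margin", n_perm=config.n_perm, seed=config.seed + 1
        )
        save(pd.concat([axis_tests, margin_tests]), "dbrda_tests.csv", index=False)

        groups = scores.loc[matrix.index, "level"]
        iv = IndicatorSpeciesAnalysis(matrix, groups).fit(
            n_perm=config.n_perm, seed=config.seed + 2
        )
        save(iv.table, "indval.csv", index=False)

        save(restrictedness(matrix).to_frame(), "restrictedness.csv")
        div = diversity_table(matrix, attrs)
        save(div, "diversity.csv")

        idi_vec = scores.loc[matrix.index, "idi"].to_numpy()
        trend_rows = []
        for col in ("abundance", "richness", "shannon", "simpson_dominance",
                    "equitability"):
            y = div[col].to_numpy(dtype=float)
            if np.isnan(y).any() or np.std(y) == 0:
                continue
            tr = trend_test(y, idi_vec, n_perm=config.n_perm,
                            seed=config.seed + 3)
            trend_rows.append(
                {"metric": col, "slope": tr.slope, "rho": tr.rho, "p": tr.p}
            )
        save(pd.DataFrame(trend_rows), "trend_tests.csv", index=False)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "package": "streamdisturb",
        "version": __version__,
        "outputs": written,
        "skipped": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                       encoding="utf-8")
    return out
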