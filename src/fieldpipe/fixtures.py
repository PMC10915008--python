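"""Deterministic synthetic data: designs, filled templates, instrument exports.

The generators emulate three realistic experimental settings so the
whole pipeline is exercisable without any external data:

* a soybean field trial — 25 genotypes x 4 replications x 2 planting
  treatments (200 plots),
* a wheat field trial — 14 genotypes x 3 replications x 3 environments
  (well-watered, drought, high temperature; 126 plots),
* a rice growth-chamber experiment — 6 genotypes x 2 CO2 levels x 2
  drought levels x 2 replications (48 pots).

Filled templates mimic data entered by hand into builder-generated
sheets; device exports mimic instrument downloads with divergent
column spellings (the classic "LAI" / "Leaf Area Index" / "lai" /
"leaf area index" situation), bookkeeping columns, and no observation
identifier — exactly the files the ETL stage exists to harmonize.
Everything is seeded: the same seed yields byte-identical files.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from fieldpipe.config_schema import TemplateConfig
from fieldpipe.errors import DataError
from fieldpipe.template_builder import (
    DesignTable,
    TemplateTable,
    build_template,
    read_design_table,
    write_template,
)

#: The four divergent spellings used to demonstrate header unification.
LAI_SPELLINGS = ("LAI", "Leaf Area Index", "lai", "leaf area index")


@dataclass
class VariableSpec:
    """One synthetic measured variable: name, units, normal(mean, sd) values."""

    name: str
    units: str
    mean: float
    sd: float


@dataclass
class FixtureSpec:
    """Parameters of one synthetic experiment."""

    crop: str
    genotypes: int
    reps: int
    treatments: Sequence[str]
    samples_per_plot: int = 1
    variables: Sequence[VariableSpec] = field(
        default_factory=lambda: [VariableSpec("plant_height", "cm", 80.0, 12.0)]
    )
    missing_rate: float = 0.0
    header_style: str = "template"  # template | lab | instrument
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotypes < 1 or self.reps < 1 or not self.treatments:
            raise DataError("genotype, replication and treatment counts must be positive")
        if self.samples_per_plot < 1:
            raise DataError("samples_per_plot must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise DataError("missing_rate must lie in [0, 1]")


def soybean_spec(seed: int = 0) -> FixtureSpec:
    """The soybean field trial: 25 genotypes x 4 reps x 2 planting dates."""
    return FixtureSpec(
        crop="soybean",
        genotypes=25,
        reps=4,
        treatments=("EP", "LP"),
        variables=[VariableSpec("canopy_height", "cm", 85.0, 10.0)],
        seed=seed,
    )


def wheat_spec(seed: int = 0) -> FixtureSpec:
    """The wheat field trial: 14 genotypes x 3 reps x 3 environments."""
    return FixtureSpec(
        crop="wheat",
        genotypes=14,
        reps=3,
        treatments=("WW", "DR", "HT"),
        variables=[VariableSpec("canopy_temperature", "C", 28.0, 2.5)],
        seed=seed,
    )


def rice_spec(seed: int = 0) -> FixtureSpec:
    """The rice growth-chamber experiment: 6 genotypes, 2 CO2 x 2 drought x 2 reps."""
    return FixtureSpec(
        crop="rice",
        genotypes=6,
        reps=2,
        treatments=("aCO2_WW", "aCO2_DR", "eCO2_WW", "eCO2_DR"),
        variables=[VariableSpec("leaf_water_potential", "MPa", -1.2, 0.4)],
        seed=seed,
    )


def generate_design_table(spec: FixtureSpec, out: str | Path) -> DesignTable:
    """Write a full-factorial design CSV (genotype x rep x treatment) and read it back.

    Plot numbers start at 101 and increase in file order, so every
    experimental-unit row is unique.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["plot,rep,genotype,treatment"]
    plot = 101
    for treatment, rep, g in itertools.product(
        spec.treatments, range(1, spec.reps + 1), range(1, spec.genotypes + 1)
    ):
        lines.append(f"{plot},{rep},G{g:03d},{treatment}")
        plot += 1
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return read_design_table(out)


def _template_config(spec: FixtureSpec, variable: VariableSpec, campaign: str) -> TemplateConfig:
    return TemplateConfig(
        template_input="",
        columns_template=["plot", "rep", "genotype", "treatment"],
        new_columns={
            "crop": spec.crop,
            "trait": variable.name,
            "units": variable.units,
            "campaign": campaign,
        },
        sample_labels=[str(i) for i in range(1, spec.samples_per_plot + 1)],
        sample_identifier=["plot", "treatment"],
        template_output=["crop", "trait", "campaign"],
    )


def generate_filled_templates(
    design: DesignTable,
    spec: FixtureSpec,
    out_dir: str | Path,
    campaigns: int = 1,
) -> list[Path]:
    """Write one filled template per (variable x campaign).

    Values are drawn from each variable's normal distribution; a
    ``missing_rate`` fraction of cells is left empty.  Observation
    identifiers follow the builder's rules, so the files are valid
    ETL inputs keyed like real collected data.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for variable in spec.variables:
        for campaign_i in range(1, campaigns + 1):
            campaign = f"C{campaign_i}"
            config = _template_config(spec, variable, campaign)
            template = build_template(design, config)
            n = len(template)
            values = rng.normal(variable.mean, variable.sd, size=n).round(2)
            missing = rng.random(n) < spec.missing_rate
            cells = ["" if m else format(v, ".2f") for v, m in zip(values, missing)]
            template.frame[template.value_column] = cells
            written.append(write_template(template, out_dir, config, overwrite=True))
    return written


def generate_device_exports(
    design: DesignTable,
    spec: FixtureSpec,
    out_dir: str | Path,
    spellings: Sequence[str] = LAI_SPELLINGS,
    seasons: Sequence[str] = ("2022",),
    campaigns: int = 1,
    extra_columns: int = 2,
    include_observation_id: bool = False,
) -> list[Path]:
    """Write instrument-style exports with divergent headers.

    One file per (treatment x season x campaign); the measurement
    column's spelling cycles through ``spellings`` across files, so a
    column report sees no shared measurement name and the rename map is
    required to unify them.  By default files carry bookkeeping columns
    (record number, battery voltage) but no identifier column,
    exercising the metadata join; with ``include_observation_id`` the
    files mimic filled builder templates instead, each row keyed by
    plot, treatment, season and campaign.
    """
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variable = spec.variables[0]
    written: list[Path] = []
    groups = list(itertools.product(spec.treatments, seasons, range(1, campaigns + 1)))
    for file_i, (treatment, season, campaign) in enumerate(groups):
        spelling = spellings[file_i % len(spellings)]
        mask = design.frame["treatment"] == treatment
        plots = design.frame.loc[mask, "plot"].tolist()
        header = []
        if include_observation_id:
            header.append("observation_id")
        header.append("record")
        if extra_columns >= 2:
            header.append("battery_v")
        header += ["plot", "season", spelling]
        lines = [",".join(header)]
        values = rng.normal(variable.mean, variable.sd, size=len(plots)).round(2)
        for rec, (plot, v) in enumerate(zip(plots, values), start=1):
            cells = []
            if include_observation_id:
                cells.append(f"{plot}_{treatment}_{season}_c{campaign:02d}")
            cells.append(str(rec))
            if extra_columns >= 2:
                cells.append(format(rng.uniform(11.5, 12.8), ".1f"))
            cells += [plot, season, format(v, ".2f")]
            lines.append(",".join(cells))
        name = f"{spec.crop}_{variable.name}_{treatment}_{season}_c{campaign:02d}.csv"
        path = out_dir / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written


def write_manifest(out_dir: str | Path, spec: FixtureSpec, files: Sequence[Path]) -> Path:
    """Record every generated file and the generation parameters that produced it."""
    out_dir = Path(out_dir)
    manifest = {
        "spec": {
            "crop": spec.crop,
            "genotypes": spec.genotypes,
            "reps": spec.reps,
            "treatments": list(spec.treatments),
            "samples_per_plot": spec.samples_per_plot,
            "variables": [
                {"name": v.name, "units": v.units, "mean": v.mean, "sd": v.sd} for v in spec.variables
            ],
            "missing_rate": spec.missing_rate,
            "header_style": spec.header_style,
            "seed": spec.seed,
        },
        "files": sorted(p.name for p in files),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def make_genotype_lookup(design: DesignTable, out: str | Path) -> Path:
    """Write a plot -> genotype lookup keyed uniquely by plot, for join testing."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    sub = design.frame[["plot", "genotype"]].drop_duplicates(subset=["plot"])
    sub.to_csv(out, index=False, lineterminator="\n")
    return out
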