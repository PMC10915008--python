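"""Shared fixtures: small designs, configs and CSV-writing helpers."""

from __future__ import annotations

from pathlib import Path

import pytest

from fieldpipe.config_schema import EtlConfig, TemplateConfig
from fieldpipe.template_builder import read_design_table


def write_csv(path: Path, text: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text.strip() + "\n", encoding="utf-8")
    return path


@pytest.fixture
def small_design(tmp_path):
    """Four plots, two treatments: the smallest design with real structure."""
    path = write_csv(
        tmp_path / "design.csv",
        """
plot,rep,genotype,treatment
101,1,G001,EP
102,1,G002,EP
201,1,G001,LP
202,1,G002,LP
""",
    )
    return read_design_table(path)


@pytest.fixture
def small_template_config():
    return TemplateConfig(
        template_input="design.csv",
        columns_template=["plot", "rep", "genotype", "treatment"],
        new_columns={"crop": "soybean", "trait": "height", "units": "cm"},
        sample_labels=["1", "2", "3"],
        sample_identifier=["plot", "treatment"],
        template_output=["crop", "trait"],
    )


@pytest.fixture
def empty_etl_config(tmp_path):
    return EtlConfig(files_to_process=str(tmp_path / "inputs"))
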