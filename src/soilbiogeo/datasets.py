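"""Bundled reference data from the 21-site China maize-soil survey.

The site table carries the environmental parameters of the 21 maize-field
soils (pH; available K, N, P and organic C, total N in mg/kg; mean annual
precipitation in mm; mean annual temperature in degrees C) together with the
decimal-degree coordinates and field-assessed soil texture class.  The
summary JSON records the survey's published headline numbers (sequence and
OTU counts, dominant-phylum percentages, network sizes) for desk-checkable
arithmetic and as reference problem sizes.
"""

from __future__ import annotations

import json
from importlib import resources

from .io import SiteMetadata, read_metadata

__all__ = ["load_maize_soil_metadata", "load_survey_summary"]


def _data_path(name: str):
    return resources.files("soilbiogeo").joinpath("data", name)


def load_maize_soil_metadata() -> SiteMetadata:
    """The 21 maize-field sites across China (coordinates + 8 covariates)."""
    with resources.as_file(_data_path("china_maize_sites.tsv")) as path:
        return read_metadata(path)


def load_survey_summary() -> dict:
    """Published summary statistics of the survey (counts, percentages, sizes)."""
    return json.loads(_data_path("survey_summary.json").read_text())
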