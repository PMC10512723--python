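"""Canonical column schemas: acoustic functionals, neuropsychology, demographics."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

#: Cutoff (pg/mL) below which CSF Abeta42 is called amyloid positive.
ABETA_CUTOFF = 796.0

#: The seven acoustic functionals highlighted by the attribution analysis,
#: under their canonical schema names.
KEY_ACOUSTIC_FEATURES = (
    "F3bandwidth_sma3nz_stddevNorm",       # F3 bandwidth (voiced) coefficient of variation
    "F2bandwidth_sma3nz_amean",            # F2 bandwidth (voiced) mean
    "hammarbergIndexUV_sma3nz_amean",      # Hammarberg index (unvoiced) mean
    "logRelF0-H1-A3_sma3nz_amean",         # harmonic difference H1-A3 (voiced) mean
    "spectralFluxV_sma3nz_stddevNorm",     # spectral flux (voiced) coefficient of variation
    "MeanVoicedSegmentLengthSec",          # voiced segment length mean
    "StddevVoicedSegmentLengthSec",        # voiced segment length std
)

#: The 13 neuropsychological battery variables used as model inputs.
NEUROPSYCH_VARIABLES = (
    "wais_digit_forward",
    "wais_digit_backward",
    "wms_delayed_recall",
    "wms_recognition",
    "objects_15",
    "poppelreuter_figures",
    "skt_time",
    "phonetic_fluency",
    "semantic_fluency",
    "wais_similarities",
    "bnt_15",
    "verbal_comprehension",
    "luria_clock",
)

#: Demographic covariates, in design-matrix order. Sex is encoded female=1.
DEMOGRAPHIC_VARIABLES = ("age", "sex", "education")


@lru_cache(maxsize=1)
def acoustic_schema() -> tuple[str, ...]:
    """Return the fixed, ordered list of 88 acoustic functional names.

    The list is the v02 functional-summary output schema of the extended
    Geneva Minimalistic Acoustic Parameter Set, shipped as package data.
    """
    text = (
        resources.files("amyvox.data")
        .joinpath("egemaps_v02_functionals.txt")
        .read_text(encoding="utf-8")
    )
    names = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(names) != len(set(names)):
        raise RuntimeError("acoustic schema contains duplicate names")
    return names
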