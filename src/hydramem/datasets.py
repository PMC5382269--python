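"""Packaged reference datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffraction import PeakFit

#: bilayer thickness (angstrom) used to convert the DGDG lamellar period to
#: a bilayer separation, from X-ray structural work on DGDG
DGDG_BILAYER_THICKNESS_A = 41.7


def dgdg_bragg_peaks_path():
    """Path to the packaged DGDG Bragg-peak table (h, q_x, delta q_x)."""
    return resources.files("hydramem").joinpath("data/dgdg_bragg_peaks.tsv")


def dgdg_bragg_peaks() -> pd.DataFrame:
    with resources.as_file(dgdg_bragg_peaks_path()) as p:
        return pd.read_csv(
            p, sep=r"\s+", comment="#", names=["h", "q_x", "dq_x"], engine="python"
        )


def dgdg_bragg_peakfits() -> list:
    """The measured peaks as :class:`PeakFit` records ready for period fits."""
    df = dgdg_bragg_peaks()
    return [
        PeakFit(
            order=int(r.h),
            center=float(r.q_x),
            center_err=float(r.dq_x),
            sigma=1e-3,
            amplitude=1.0,
            background=0.0,
        )
        for r in df.itertuples()
    ]
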