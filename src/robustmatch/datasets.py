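"""Bundled reference tables for the *L. lactis* MG1363 fermentation study.

The package ships three small plain-text tables: the 13-fermentation
combinatorial design with its measured growth characteristics, and the two
published robustness signatures (heat and oxidative stress) with per-gene
correlation directions.  These are the fixtures used by the worked examples
and by the acceptance checks; they are loaded with :mod:`importlib.resources`
so they work from an installed package as well as a source checkout.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_fermentation_table",
    "load_signature_table",
    "FACTOR_COLUMNS",
]

#: Design-factor column names shared by every design table in the package.
FACTOR_COLUMNS = ["nacl_mM", "start_pH", "temperature_C", "aeration"]

_STRESSES = ("heat", "oxidative")


def _read_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("robustmatch.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"aeration": str})


def load_fermentation_table() -> pd.DataFrame:
    """Return the 13-row fermentation design with growth characteristics.

    Columns: ``fermentation_id``, ``nacl_mM`` (0 or 100), ``start_pH``
    (6.0 or 6.5), ``temperature_C`` (27, 30 or 35), ``aeration``
    (``+`` shaken / ``-`` static), ``od_final`` and ``mu_max`` (h^-1).
    Fermentation 13 is a replicate of fermentation 6.
    """
    return _read_bundled("mg1363_fermentations.tsv")


def load_signature_table(stress: str) -> pd.DataFrame:
    """Return the published robustness signature for ``stress``.

    Parameters
    ----------
    stress
        ``"heat"`` (18 genes) or ``"oxidative"`` (54 genes).

    Returns
    -------
    DataFrame with columns ``locus_tag``, ``gene`` (may be empty) and
    ``direction`` (``positive``/``negative`` correlation with robustness).
    """
    if stress not in _STRESSES:
        raise ValueError(f"stress must be one of {_STRESSES}, got {stress!r}")
    df = _read_bundled(f"mg1363_{stress}_signature.tsv")
    return df.fillna({"gene": ""})
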