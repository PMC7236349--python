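"""Bundled published substitution models.

The general models (Dayhoff, JTT, LG, WAG) and the mitochondrial models
(mtREV, mtArt, mtZoa) are bundled verbatim at their published scales, as
distributed in PAML-format data files.  mtOrt, the Orthoptera
mitochondrial model, is bundled at the precision of its published table
(two decimals); the five pair rates that print as 0.00 are reconstructed —
Arg-Phe carries its separately published value 0.00005 (the model's
minimum) and the remaining four (Lys-Ala, Lys-Cys, Pro-Cys, Val-His) are
set to 0.001, inside the printed rounding band.  The published frequency
row sums to 1.02 and is renormalized on load.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .model_io import read_model_file
from .models import SubstitutionModel

_SOURCES = {
    "Dayhoff": "Dayhoff, Schwartz & Orcutt 1978 (PAM)",
    "JTT": "Jones, Taylor & Thornton 1992",
    "LG": "Le & Gascuel 2008",
    "WAG": "Whelan & Goldman 2001",
    "mtREV": "Adachi & Hasegawa 1996 (mtREV24)",
    "mtArt": "Abascal, Posada & Zardoya 2007",
    "mtZoa": "Rota-Stabelli, Yang & Telford 2009",
    "mtOrt": "Orthoptera mitochondrial model (2020), published two-decimal precision",
}

_CANONICAL = {name.lower(): name for name in _SOURCES}


def available_models() -> list[str]:
    """Names of all bundled models, in registry order."""
    return list(_SOURCES)


@lru_cache(maxsize=None)
def get_model(name: str) -> SubstitutionModel:
    """Load a bundled model by (case-insensitive) name."""
    try:
        canonical = _CANONICAL[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(available_models())}"
        ) from None
    ref = resources.files("aamodel.data").joinpath(f"{canonical}.dat")
    with resources.as_file(ref) as path:
        model = read_model_file(path, format="paml_dat", name=canonical)
    return SubstitutionModel(
        canonical, model.exchangeabilities, model.frequencies,
        source=_SOURCES[canonical],
    )
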