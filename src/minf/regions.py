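"""Packaged list of the 48 ICBM Mori (JHU ICBM-DTI-81) white-matter region names.

The list is a configuration file shipped with the package, not hard-coded
truth: the label-value -> name mapping of a given atlas build may differ, and
callers can supply their own ordered name list wherever region names are
accepted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

N_REGIONS = 48

FORNIX = "Fornix (column and body of fornix)"
LEFT_ANTERIOR_CORONA_RADIATA = "Anterior corona radiata L"
MIDDLE_CEREBELLAR_PEDUNCLE = "Middle cerebellar peduncle"


@lru_cache(maxsize=1)
def region_names() -> tuple[str, ...]:
    """Return the 48 region names ordered by atlas label value (1..48)."""
    text = (
        resources.files("minf.data").joinpath("icbm_mori_regions.txt").read_text()
    )
    names = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(names) != N_REGIONS:
        raise RuntimeError(f"packaged region list has {len(names)} entries, expected {N_REGIONS}")
    return tuple(names)


def region_label_map() -> dict[int, str]:
    """Map integer atlas label (1-based) to region name."""
    return {i + 1: name for i, name in enumerate(region_names())}
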