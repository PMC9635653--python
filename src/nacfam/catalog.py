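"""Reference catalogue of functionally characterized defense-associated NACs.

The packaged table lists the NAC genes from wheat, barley, rice and
*Arabidopsis* with genetic evidence (silencing, overexpression, insertion
lines, ...) for a role in pathogen defense, together with the subfamily each
falls into on the joined phylogeny.  It anchors subfamily interpretation:
query genes landing next to catalogue members inherit a defense hypothesis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CATALOG_FILE = "characterized_nacs.tsv"


def load_characterized_catalog() -> pd.DataFrame:
    """Catalogue of characterized defense NACs (one row per gene)."""
    ref = resources.files("nacfam") / "data" / _CATALOG_FILE
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def catalog_summary(catalog: pd.DataFrame | None = None) -> dict[str, int]:
    """Headline counts: total genes, per-subfamily and per-species tallies."""
    cat = load_characterized_catalog() if catalog is None else catalog
    out = {"total": int(len(cat))}
    for sf, n in cat["subfamily"].value_counts().items():
        out[f"subfamily_{sf}"] = int(n)
    for sp, n in cat["species"].value_counts().items():
        out[f"species_{sp.split()[0]}_{sp.split()[1]}"] = int(n)
    return out
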