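"""Uniparental-marker ancestry tallies and the MT / autosome / Y comparison.

Mitochondria pass strictly through the maternal line and Y chromosomes
through the paternal line, so comparing the ancestry composition of MT
haplogroups, autosomes and Y haplogroups orders the female vs male
contribution of each source population: an ancestry with
f_MT > f_auto > f_Y entered predominantly through women, the reverse
ordering through men. Haplogroup-to-ancestry assignments are supplied as an
input table, never inferred here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tally_marker_ancestry(
    haps: pd.DataFrame,
    marker: str,
    ancestry_labels: list[str],
    site: str | None = None,
    individual_sites: pd.Series | None = None,
) -> dict:
    """Ancestry frequencies among the haplogroup assignments of one marker.

    ``haps`` has columns individual_id, marker, haplogroup, ancestry. With
    ``site`` given, ``individual_sites`` (individual_id -> site) restricts
    the tally. Haplogroups whose ancestry is missing or outside
    ``ancestry_labels`` raise an error listing the offenders.
    """
    if marker not in ("MT", "Y"):
        raise ValueError("marker must be 'MT' or 'Y'")
    sub = haps[haps["marker"] == marker]
    if site is not None:
        if individual_sites is None:
            raise ValueError("individual_sites needed for a site-restricted tally")
        ids = set(individual_sites[individual_sites == site].index)
        sub = sub[sub["individual_id"].isin(ids)]
    if len(sub) == 0:
        raise ValueError(f"no {marker} assignments for site {site or 'ALL'}")
    unknown = sub[~sub["ancestry"].isin(ancestry_labels) | sub["ancestry"].isna()]
    if len(unknown):
        offenders = sorted(unknown["haplogroup"].unique())
        raise ValueError(f"haplogroups with no ancestry mapping: {offenders}")
    counts = sub["ancestry"].value_counts()
    n = int(counts.sum())
    freqs = {lab: float(counts.get(lab, 0)) / n for lab in ancestry_labels}
    return {"marker": marker, "site": site or "ALL", "n": n, **freqs}


def three_marker_comparison(
    mt_tally: dict | None,
    auto_means: dict,
    y_tally: dict | None,
    ancestry_labels: list[str],
    site: str = "ALL",
) -> pd.DataFrame:
    """Per-ancestry (f_MT, f_auto, f_Y) with a sex-lean ordering flag.

    'female-leaning' where f_MT > f_auto > f_Y, 'male-leaning' where the
    ordering is reversed, 'mixed' otherwise, and 'insufficient' where the MT
    or Y tally is unavailable.
    """
    rows = []
    for lab in ancestry_labels:
        f_mt = mt_tally.get(lab) if mt_tally else None
        f_auto = float(auto_means[lab])
        f_y = y_tally.get(lab) if y_tally else None
        if f_mt is None or f_y is None:
            flag = "insufficient"
        elif f_mt > f_auto > f_y:
            flag = "female-leaning"
        elif f_mt < f_auto < f_y:
            flag = "male-leaning"
        else:
            flag = "mixed"
        rows.append(
            {
                "site": site,
                "ancestry": lab,
                "f_mt": np.nan if f_mt is None else f_mt,
                "f_auto": f_auto,
                "f_y": np.nan if f_y is None else f_y,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def validate_y_rows_male(haps: pd.DataFrame, sexes: pd.Series) -> None:
    """Ensure Y-marker rows belong to male individuals (sexes: id -> M/F)."""
    y_rows = haps[haps["marker"] == "Y"]
    bad = [
        iid
        for iid in y_rows["individual_id"]
        if sexes.get(iid, "U") != "M"
    ]
    if bad:
        raise ValueError(f"Y haplogroup rows for non-male individuals: {sorted(set(bad))}")
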