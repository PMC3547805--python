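"""Swiss cantons and their grouping into the seven major regions.

The 26 canton abbreviations are standard; the region grouping follows the
large-region classification (Lake Geneva, Espace Mittelland, Northwestern,
Zurich, Eastern, Central, Ticino). Canton population weights are not
modelled: the synthetic generator samples cantons uniformly by default.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "Lake Geneva",
    "Espace Mittelland",
    "Northwestern",
    "Zurich",
    "Eastern",
    "Central",
    "Ticino",
)

CANTON_TO_REGION: dict[str, str] = {
    # Lake Geneva
    "GE": "Lake Geneva", "VD": "Lake Geneva", "VS": "Lake Geneva",
    # Espace Mittelland
    "BE": "Espace Mittelland", "FR": "Espace Mittelland",
    "SO": "Espace Mittelland", "NE": "Espace Mittelland",
    "JU": "Espace Mittelland",
    # Northwestern Switzerland
    "BS": "Northwestern", "BL": "Northwestern", "AG": "Northwestern",
    # Zurich
    "ZH": "Zurich",
    # Eastern Switzerland
    "GL": "Eastern", "SH": "Eastern", "AR": "Eastern", "AI": "Eastern",
    "SG": "Eastern", "GR": "Eastern", "TG": "Eastern",
    # Central Switzerland
    "LU": "Central", "UR": "Central", "SZ": "Central", "OW": "Central",
    "NW": "Central", "ZG": "Central",
    # Ticino
    "TI": "Ticino",
}

CANTONS: tuple[str, ...] = tuple(sorted(CANTON_TO_REGION))

assert len(CANTONS) == 26
assert set(CANTON_TO_REGION.values()) == set(REGIONS)
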