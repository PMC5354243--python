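"""Canonical metabolite panel definition.

The 24-variable folate-dependent one-carbon metabolism / transsulfuration
(FOCM/TS) panel, with the four ratio variables that are exact functions of
other panel members.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Canonical variable names, in canonical order.
PANEL_24: tuple[str, ...] = (
    "Methionine",
    "SAM",
    "SAH",
    "SAM/SAH",
    "% DNA methylation",
    "8-OHG",
    "Adenosine",
    "Homocysteine",
    "Cysteine",
    "Glu.-Cys.",
    "Cys.-Gly.",
    "tGSH",
    "fGSH",
    "GSSG",
    "fGSH/GSSG",
    "tGSH/GSSG",
    "Chlorotyrosine",
    "Nitrotyrosine",
    "Tyrosine",
    "Tryptophane",
    "fCystine",
    "fCysteine",
    "fCystine/fCysteine",
    "% oxidized glutathione",
)

#: Ratio variable -> (numerator, denominator), all canonical names.
RATIO_COMPONENTS: dict[str, tuple[str, str]] = {
    "SAM/SAH": ("SAM", "SAH"),
    "fGSH/GSSG": ("fGSH", "GSSG"),
    "tGSH/GSSG": ("tGSH", "GSSG"),
    "fCystine/fCysteine": ("fCystine", "fCysteine"),
}

#: Cohort labels, canonical spelling.
COHORTS: tuple[str, str, str] = ("ASD", "SIB", "NEU")


def normalize_name(name: str) -> str:
    """Collapse case, whitespace and punctuation for alias matching."""
    return re.sub(r"[^a-z0-9%/]+", "", name.strip().lower())


@dataclass(frozen=True)
class MetabolitePanel:
    """An ordered, unique set of variable names with ratio metadata.

    Parameters
    ----------
    names:
        Ordered variable names. Defaults to the canonical 24-variable panel.
    ratio_components:
        Mapping of ratio variables present in ``names`` to the
        (numerator, denominator) names they are derived from.
    """

    names: tuple[str, ...] = PANEL_24
    ratio_components: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(RATIO_COMPONENTS)
    )

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("panel names must be unique")
        if not self.names:
            raise ValueError("panel must contain at least one variable")
        for ratio, (num, den) in self.ratio_components.items():
            if ratio not in self.names:
                raise ValueError(f"ratio variable {ratio!r} not in panel")
            for comp in (num, den):
                if comp != ratio and comp not in self.names and comp in PANEL_24:
                    # component may legitimately be absent from a reduced panel
                    pass

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)

    def checkable_ratios(self) -> dict[str, tuple[str, str]]:
        """Ratios whose numerator and denominator are both in the panel."""
        return {
            r: (n, d)
            for r, (n, d) in self.ratio_components.items()
            if r in self.names and n in self.names and d in self.names
        }

    @classmethod
    def default(cls) -> "MetabolitePanel":
        return cls()

    @classmethod
    def reduced(cls, names: list[str] | tuple[str, ...]) -> "MetabolitePanel":
        """Panel restricted to ``names``, keeping applicable ratio metadata."""
        names = tuple(names)
        ratios = {
            r: c for r, c in RATIO_COMPONENTS.items() if r in names
        }
        return cls(names=names, ratio_components=ratios)


#: Canonical-name lookup keyed by the normalized form.
_CANONICAL_BY_NORMALIZED: dict[str, str] = {
    normalize_name(n): n for n in PANEL_24
}

#: Extra aliases that normalization alone does not resolve.
DEFAULT_ALIASES: dict[str, str] = {
    "dnamethylation": "% DNA methylation",
    "percentdnamethylation": "% DNA methylation",
    "pctdnamethylation": "% DNA methylation",
    "8ohg": "8-OHG",
    "8ohguanosine": "8-OHG",
    "glucys": "Glu.-Cys.",
    "glutamylcysteine": "Glu.-Cys.",
    "cysgly": "Cys.-Gly.",
    "cysteinylglycine": "Cys.-Gly.",
    "oxidizedglutathione": "% oxidized glutathione",
    "percentoxidizedglutathione": "% oxidized glutathione",
    "pctoxidizedglutathione": "% oxidized glutathione",
    "tryptophan": "Tryptophane",
    "chlorotyrosine": "Chlorotyrosine",
    "3chlorotyrosine": "Chlorotyrosine",
    "3nitrotyrosine": "Nitrotyrosine",
}


def resolve_variable(name: str, extra_aliases: dict[str, str] | None = None) -> str | None:
    """Map a raw column header to a canonical panel name, or None."""
    key = normalize_name(name)
    if extra_aliases:
        extra = {normalize_name(k): v for k, v in extra_aliases.items()}
        if key in extra:
            return extra[key]
    if key in _CANONICAL_BY_NORMALIZED:
        return _CANONICAL_BY_NORMALIZED[key]
    return DEFAULT_ALIASES.get(key)
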