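"""ICD-10 underlying-cause grouping and cause-specific mortality rates.

Groups follow the international collaborative effort (ICE) style
cause-of-death classification for infants.  The shipped default mapping is
an approximation assembled from the usual group definitions (immaturity-
related conditions, congenital anomalies, asphyxia, infection, SIDS,
external causes, other/ill-defined); it is reference data, replaceable via
a YAML file, and the grouping engine is independent of its content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
import yaml

from .rates import mortality_rate, rate_table

UNCLASSIFIABLE = "unclassifiable"
FALLBACK_GROUP = "other/ill-defined"

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")


def _expand(prefixes) -> tuple[str, ...]:
    """Expand 'P26-P28' style ranges into explicit prefixes."""
    out = []
    for p in prefixes:
        m = re.match(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$", p)
        if m:
            a_letter, a_num, b_letter, b_num = m.groups()
            if a_letter != b_letter:
                raise ValueError(f"range {p!r} must stay within one letter")
            out.extend(f"{a_letter}{i:02d}"
                       for i in range(int(a_num), int(b_num) + 1))
        else:
            out.append(p)
    return tuple(out)


@dataclass
class ICEMapping:
    """Ordered (group label, ICD-10 code prefixes) pairs with a fallback
    group; prefix sets must be pairwise disjoint so every valid code maps
    to exactly one group."""

    groups: list[tuple[str, tuple[str, ...]]]
    fallback: str = FALLBACK_GROUP

    def __post_init__(self) -> None:
        self.groups = [(label, _expand(prefixes))
                       for label, prefixes in self.groups]
        flat = [p for _, ps in self.groups for p in ps]
        for i, a in enumerate(flat):
            for b in flat[i + 1:]:
                if a.startswith(b) or b.startswith(a):
                    raise ValueError(
                        f"prefix sets not disjoint: {a!r} vs {b!r}")

    def labels(self) -> list[str]:
        return [label for label, _ in self.groups] + [self.fallback]

    @classmethod
    def default(cls) -> "ICEMapping":
        return cls(groups=[
            ("immaturity-related",
             ("P05", "P07", "P22", "P26-P28", "P77")),
            ("congenital anomalies", ("Q",)),
            ("asphyxia", ("P03", "P10", "P15", "P20-P21", "P24")),
            ("infection", ("A", "B", "J", "P23", "P35-P39")),
            ("SIDS", ("R95",)),
            ("external", ("V", "W", "X", "Y")),
        ])

    @classmethod
    def from_yaml(cls, path) -> "ICEMapping":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        groups = [(g["label"], tuple(g["prefixes"])) for g in data["groups"]]
        return cls(groups=groups, fallback=data.get("fallback", FALLBACK_GROUP))


def assign_group(icd10: str, mapping: ICEMapping | None = None) -> str:
    """Map one ICD-10 code to its cause group by longest-prefix match;
    unmatched valid codes fall into the fallback group, malformed codes are
    'unclassifiable'."""
    mapping = mapping or ICEMapping.default()
    code = (icd10 or "").strip().upper().replace(".", "")
    if not _ICD10_RE.match(code):
        return UNCLASSIFIABLE
    best_label, best_len = mapping.fallback, 0
    for label, prefixes in mapping.groups:
        for p in prefixes:
            if code.startswith(p) and len(p) > best_len:
                best_label, best_len = label, len(p)
    return best_label


def assign_groups(codes: pd.Series, mapping: ICEMapping | None = None) -> pd.Series:
    mapping = mapping or ICEMapping.default()
    return codes.map(lambda c: assign_group(c, mapping))


def cause_specific_rates(all_deaths: pd.DataFrame, denominator_n: int,
                         mapping: ICEMapping | None = None,
                         scale: float = 1000.0, suppress_at: int = 5,
                         alpha: float = 0.05, method: str = "midp"
                         ) -> pd.DataFrame:
    """Cause-group-specific infant mortality rates over ALL registered
    deaths (linked and unlinked) per 1000 live births; groups with <= 5
    deaths are flagged suppressed."""
    if denominator_n <= 0:
        raise ValueError("denominator must be positive")
    mapping = mapping or ICEMapping.default()
    groups = assign_groups(all_deaths["icd10_cause"], mapping)
    rows = [(label, int((groups == label).sum()), denominator_n)
            for label in mapping.labels() + [UNCLASSIFIABLE]]
    table = rate_table(rows, scale=scale, suppress_at=suppress_at,
                       alpha=alpha, method=method)
    table = table.sort_values("rate", ascending=False).reset_index(drop=True)
    table.attrs["n_deaths"] = len(all_deaths)
    return table
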