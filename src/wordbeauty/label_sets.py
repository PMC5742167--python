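"""Default label sets for the relatedness-contrast features.

Two scores are computed as signed semantic-relatedness contrasts against
named label sets:

* **valence** — positivity/negativity, contrasted against a 36-label set
  (18 positive, 18 negative);
* **aesthetic potential (AP)** — the word-beauty score, contrasted against a
  larger 124-label aesthetic vocabulary (62 positive, 62 negative).

The lists below are editable defaults in the spirit of the published label
counts (words such as *anmut* 'grace' and *freude* 'joy' anchor the positive
aesthetic pole); they are configuration data, not a canonical norm list, and
can be replaced wholesale via :meth:`LabelSetConfig.from_file`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

__all__ = ["LabelSetConfig", "default_valence_labels", "default_ap_labels"]


@dataclass(frozen=True)
class LabelSetConfig:
    """A named pair of disjoint positive/negative label word lists."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError(f"label set {self.name!r}: both poles must be non-empty")
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"label set {self.name!r}: labels on both poles: {sorted(overlap)[:5]}"
            )

    @property
    def n_labels(self) -> int:
        return len(self.positive) + len(self.negative)

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelSetConfig":
        """Read a simple key/value config::

            name: valence
            positive: glück, freude, ...
            negative: hass, angst, ...

        Lists may span several lines (continuation lines are indented or
        contain no ``:``); ``#`` starts a comment.
        """
        text = Path(path).read_text(encoding="utf-8")
        fields: dict[str, str] = {}
        current: str | None = None
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].rstrip()
            if not line.strip():
                continue
            m = re.match(r"^(name|positive|negative)\s*:\s*(.*)$", line)
            if m:
                current = m.group(1)
                fields[current] = m.group(2)
            elif current is not None:
                fields[current] += " " + line.strip()
            else:
                raise ValueError(f"{path}: unexpected line before any key: {line!r}")
        missing = {"name", "positive", "negative"} - set(fields)
        if missing:
            raise ValueError(f"{path}: missing keys: {sorted(missing)}")
        split = lambda s: tuple(w.strip().lower() for w in re.split(r"[,\s]+", s) if w.strip())
        return cls(fields["name"].strip(), split(fields["positive"]), split(fields["negative"]))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"name: {self.name}\n")
            fh.write("positive: " + ", ".join(self.positive) + "\n")
            fh.write("negative: " + ", ".join(self.negative) + "\n")


_VALENCE_POSITIVE = (
    "glück", "freude", "liebe", "hoffnung", "vertrauen", "lachen",
    "geschenk", "freund", "familie", "urlaub", "erfolg", "gesundheit",
    "genuss", "spass", "feier", "umarmung", "kuss", "sieg",
)

_VALENCE_NEGATIVE = (
    "hass", "angst", "trauer", "schmerz", "krieg", "tod",
    "verlust", "krankheit", "streit", "lüge", "verrat", "neid",
    "wut", "scham", "schuld", "elend", "armut", "folter",
)

_AP_POSITIVE = (
    "anmut", "freude", "glanz", "zauber", "harmonie", "melodie",
    "blüte", "morgenröte", "libelle", "sommer", "frühling", "sonne",
    "licht", "sanftheit", "zärtlichkeit", "liebreiz", "heiterkeit",
    "schönheit", "eleganz", "grazie", "wohlklang", "duft", "blume",
    "rose", "schmetterling", "regenbogen", "stern", "himmel", "meer",
    "welle", "perle", "seide", "samt", "gold", "silber", "kristall",
    "quelle", "bach", "wiese", "hain", "dämmerung", "abendrot",
    "mondschein", "sehnsucht", "geborgenheit", "wärme", "frieden",
    "stille", "musse", "traum", "poesie", "lied", "klang", "schimmer",
    "funkeln", "leuchten", "blühen", "schweben", "tanz", "lächeln",
    "wonne", "zauberwald",
)

_AP_NEGATIVE = (
    "ekel", "schmutz", "dreck", "gestank", "fäulnis", "schleim",
    "eiter", "abschaum", "unrat", "müll", "morast", "schlamm",
    "ratte", "made", "wanze", "zecke", "schimmel", "moder",
    "verwesung", "kadaver", "aas", "geschwür", "ausschlag", "grind",
    "rotz", "speichel", "schweiss", "furunkel", "warze", "kröte",
    "qualle", "egel", "wurm", "spucke", "jauche", "kloake", "abfall",
    "staub", "russ", "qualm", "smog", "lärm", "kreischen",
    "quietschen", "gekreisch", "krach", "missklang", "hässlichkeit",
    "plumpheit", "stumpfheit", "ödnis", "tristesse", "grauen",
    "matsch", "pfütze", "bodensatz", "schlacke", "gift", "galle",
    "geifer", "brechreiz", "gosse",
)


def default_valence_labels() -> LabelSetConfig:
    """The default 36-label valence set (18 positive / 18 negative)."""
    return LabelSetConfig("valence", _VALENCE_POSITIVE, _VALENCE_NEGATIVE)


def default_ap_labels() -> LabelSetConfig:
    """The default 124-label aesthetic-potential set (62 positive / 62 negative)."""
    return LabelSetConfig("aesthetic_potential", _AP_POSITIVE, _AP_NEGATIVE)
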