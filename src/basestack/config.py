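"""Pipeline configuration: thresholds, synonym lists, logging.

A single flat key-value file (``key = value`` lines, ``#`` comments) can
override any default; lists are comma-separated.  Distances are Angstrom,
angles degrees.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path

log = logging.getLogger("basestack")


@dataclasses.dataclass
class Config:
    # residue names recognised as 5-methyl-2'-deoxycytidine
    mc_residue_names: tuple[str, ...] = ("5CM", "C5M", "5MC")
    # synonyms for the 5-methyl carbon atom, mapped onto a canonical name
    mc_methyl_names: tuple[str, ...] = ("C5A", "C5M", "C7", "CM5")
    mc_methyl_canonical: str = "C5M"
    # base-pair detection
    c1c1_min: float = 8.0
    c1c1_max: float = 12.0
    pair_origin_max: float = 2.5
    pair_zdot_max: float = -0.6
    # hydrogen-bond heavy-atom cutoff
    hbond_max: float = 3.5
    # stacking: clipping epsilon and overlap convention
    clip_eps: float = 1e-9
    union_overlap: bool = False  # sensitivity: union-vs-union intersection
    # helix axis: per-step mid-frame z (default) or global best-fit axis
    global_helix_axis: bool = False


DEFAULT = Config()

_LIST_FIELDS = {"mc_residue_names", "mc_methyl_names"}
_BOOL_FIELDS = {"union_overlap", "global_helix_axis"}


def load_config(path: str | Path) -> Config:
    """Read a key-value config file, falling back to defaults."""
    kwargs: dict = {}
    names = {f.name for f in dataclasses.fields(Config)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in names:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _LIST_FIELDS:
            kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key in _BOOL_FIELDS:
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif key == "mc_methyl_canonical":
            kwargs[key] = value
        else:
            kwargs[key] = float(value)
    return Config(**kwargs)


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.WARNING)
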