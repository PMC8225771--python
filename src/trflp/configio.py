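"""Enzyme/primer/run configuration.

Default constants: AluI (AG^CT) and Hpy188III (TC^NNGA) with REBASE-standard
recognition patterns and top-strand cut offsets, and the degenerate-tagged
FTHFS primer pair used for acetogen community profiling.  Everything is
overridable from a YAML file so any enzyme or primer set can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .binning import BinningConfig
from .peaks import NoiseConfig
from .refdigest import Enzyme, Primer

DEFAULT_ENZYMES: dict[str, Enzyme] = {
    "AluI": Enzyme(name="AluI", site="AGCT", cut_offset=2),
    "Hpy188III": Enzyme(name="Hpy188III", site="TCNNGA", cut_offset=2),
}

#: degenerate-tagged FTHFS primer pair (23 bp each); the forward primer
#: carries the FAM label that defines the detected terminal fragment.
DEFAULT_FWD_PRIMER = Primer(name="FTHFS_fwd", seq="CCNACNCCNNNNGGNGANGGNAA", label="FAM")
DEFAULT_REV_PRIMER = Primer(name="FTHFS_rev", seq="ATNTTNGCNAANGGNCCNCCNTG")


def load_enzyme_config(
    path: str | Path,
) -> tuple[dict[str, Enzyme], dict[str, Primer]]:
    """Load ``enzymes: [{name, site, cut_offset}]`` and
    ``primers: {fwd: {...}, rev: {...}}`` from YAML; entries missing from
    the file fall back to the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    enzymes = dict(DEFAULT_ENZYMES)
    for entry in raw.get("enzymes", ()):
        enz = Enzyme(
            name=entry["name"], site=entry["site"], cut_offset=int(entry["cut_offset"])
        )
        enzymes[enz.name] = enz
    primers = {"fwd": DEFAULT_FWD_PRIMER, "rev": DEFAULT_REV_PRIMER}
    for key in ("fwd", "rev"):
        entry = raw.get("primers", {}).get(key)
        if entry:
            primers[key] = Primer(
                name=entry.get("name", key),
                seq=entry["seq"],
                label=entry.get("label"),
            )
    if primers["fwd"].label and primers["rev"].label:
        raise ValueError("at most one primer in a pair may carry a label")
    return enzymes, primers


def get_enzyme(enzyme: Union[str, Enzyme], enzymes: Optional[dict[str, Enzyme]] = None) -> Enzyme:
    """Resolve an enzyme by name against a config dict (defaults included)."""
    if isinstance(enzyme, Enzyme):
        return enzyme
    table = enzymes or DEFAULT_ENZYMES
    if enzyme not in table:
        raise KeyError(
            f"unknown enzyme {enzyme!r}; known: {sorted(table)} "
            f"(add it via the enzyme config YAML)"
        )
    return table[enzyme]


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs, loadable from one YAML."""

    reference_fasta: str
    taxonomy_tsv: str
    peak_csv: list[str]
    output_dir: str
    covariates_tsv: Optional[str] = None
    enzyme: str = "AluI"
    semantics: str = "guaranteed"
    dye: Optional[str] = "B"
    permissive_taxonomy: bool = False
    binning: BinningConfig = field(default_factory=BinningConfig)
    binning_mode: str = "pooled"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    metric: str = "euclidean"
    n_axes: int = 2
    seed: int = 0
    enzyme_config: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw = dict(raw or {})
        peak_csv = raw.get("peak_csv", [])
        if isinstance(peak_csv, str):
            peak_csv = [peak_csv]
        binning = BinningConfig(**raw.get("binning", {}))
        noise = NoiseConfig(**raw.get("noise", {}))
        known = {
            k: raw[k]
            for k in (
                "reference_fasta", "taxonomy_tsv", "output_dir", "covariates_tsv",
                "enzyme", "semantics", "dye", "permissive_taxonomy",
                "binning_mode", "metric", "n_axes", "seed", "enzyme_config",
            )
            if k in raw
        }
        return cls(peak_csv=list(peak_csv), binning=binning, noise=noise, **known)

    def to_dict(self) -> dict:
        return asdict(self)
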