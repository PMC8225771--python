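"""End-to-end orchestration: digest -> bin (IS), peaks -> noise -> RA ->
bin (Ex), match, ordinate, with a provenance manifest.

Every artifact is a TSV (or JSON for the manifest); the manifest records
the tool version, the full configuration echo and a sha256 per artifact
so a run can be verified byte-for-byte.  On any stage failure the partial
outputs are removed and the error names the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .binning import TRFMultiset, bin_profile, cluster_moving_average, filter_size_range, write_otrf_table
from .compare import export_comparison, match_ex_to_is
from .configio import (
    DEFAULT_FWD_PRIMER,
    DEFAULT_REV_PRIMER,
    RunConfig,
    get_enzyme,
    load_enzyme_config,
)
from .ordination import distance, pcoa, write_ordination
from .peaks import read_peak_csv, process_samples
from .refdigest import digest_dataset, read_reference, write_fragments_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full analysis and return the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def artifact(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    if config.enzyme_config:
        enzymes, primers = load_enzyme_config(config.enzyme_config)
    else:
        enzymes = None
        primers = {"fwd": DEFAULT_FWD_PRIMER, "rev": DEFAULT_REV_PRIMER}
    enzyme = get_enzyme(config.enzyme, enzymes)

    try:
        stage = "read_reference"
        records = read_reference(
            config.reference_fasta, config.taxonomy_tsv,
            permissive=config.permissive_taxonomy,
        )

        stage = "digest"
        profile = digest_dataset(
            records, primers["fwd"], primers["rev"], enzyme, config.semantics,
            dataset_id="reference",
        )
        write_fragments_tsv(profile, artifact("is_fragments.tsv"))

        stage = "bin_is"
        is_multiset = filter_size_range(
            TRFMultiset.from_fragments(profile), config.binning
        )
        is_otrfs = cluster_moving_average(is_multiset, config.binning)
        is_table = bin_profile(profile, config.binning, mode=config.binning_mode)
        write_otrf_table(is_table, artifact("is_otrf.tsv"),
                         sidecar=artifact("is_otrf_members.tsv"))

        stage = "peaks"
        ra_by_sample: dict[str, dict[int, float]] = {}
        for csv in config.peak_csv:
            table = read_peak_csv(csv)
            for name, ra in process_samples(
                table, dye=config.dye, noise=config.noise
            ).items():
                ra_by_sample[name] = ra

        stage = "bin_ex"
        ex_table = bin_profile(
            {name: TRFMultiset.from_abundances(ra) for name, ra in ra_by_sample.items()},
            config.binning, normalise=True, mode=config.binning_mode,
            enzyme=enzyme.name,
        )
        write_otrf_table(ex_table, artifact("ex_otrf.tsv"))

        stage = "compare"
        comparison = match_ex_to_is(
            ex_table, is_multiset, is_otrfs, config.binning.window,
            ex_enzyme=enzyme.name, is_enzyme=enzyme.name,
        )
        export_comparison(comparison, artifact("comparison.tsv"))

        stage = "ordinate"
        dm = distance(ex_table, config.metric)
        dm.to_frame().to_csv(artifact("distance_matrix.tsv"), sep="\t")
        covariates = None
        if config.covariates_tsv:
            covariates = pd.read_csv(config.covariates_tsv, sep="\t", index_col=0)
        result = pcoa(dm, config.n_axes, covariates=covariates)
        write_ordination(result, artifact("pcoa_coordinates.tsv"),
                         artifact("pcoa_eigenvalues.tsv"))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest = {
        "tool": "trflp",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": [
            {"path": p.name, "sha256": _sha256(p)} for p in written
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(written), out)
    return manifest
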