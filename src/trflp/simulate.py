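"""Synthetic fixtures: reference database, reactor community time-series,
and simulated electropherograms with known ground truth.

The generator emulates the anaerobic-digester study design every stage of
this toolkit is meant for: a reference set of marker-gene amplicons with
known taxonomy and exactly one planted restriction site each, two reactor
time-series (a stable control, and a disturbed reactor whose designated
taxa rise and fall inside a disturbance window while a volatile-fatty-acid
covariate mirrors the perturbation), and Peak-Scanner-style peak tables
with Gaussian size-calling jitter, per-peak amplification noise, an
internal-standard ladder on the orange channel, and sub-threshold noise
peaks.

All randomness flows from ``SimConfig.seed``; re-running with the same
seed reproduces every output byte for byte.  Planted fragment sizes are
*even* integers spaced at least ``trf_min_gap`` apart so that, under the
default +-2 bp binning, each taxon maps to exactly one oTRF label equal
to its planted size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .configio import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER, get_enzyme
from .iupac import IUPAC_SETS, reverse_complement
from .refdigest import (
    Enzyme,
    Primer,
    ReferenceRecord,
    find_sites,
    tag_with_primers,
)
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

_PHYLA = (
    ("Firmicutes", "Clostridia", "Eubacteriales", "Clostridiaceae"),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Microbacteriaceae"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    ("Spirochaetota", "Spirochaetia", "Spirochaetales", "Treponemataceae"),
)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults emulate the desk-scale
    two-reactor experiment (20 taxa, 12 timepoints, disturbance in the
    middle third of the series)."""

    seed: int = 1
    n_taxa: int = 20
    insert_len_range: tuple[int, int] = (520, 600)
    gc: float = 0.5
    enzyme: str = "AluI"
    trf_range: tuple[int, int] = (60, 516)
    trf_min_gap: int = 8
    n_timepoints: int = 12
    disturbance_window: tuple[int, int] = (3, 9)  # half-open timepoint indices
    n_disturbed_taxa: int = 3
    peak_fold: float = 8.0
    dirichlet_alpha: float = 5.0
    drift_sd: float = 0.05
    size_jitter_sd: float = 0.4
    noise_rate: float = 3.0
    noise_ceiling: float = 0.5  # fraction of min_proportion * total signal
    amplification_sd: float = 0.15
    total_signal: float = 50000.0
    min_proportion: float = 0.005

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        lo, hi = self.disturbance_window
        if not (0 <= lo <= hi <= self.n_timepoints):
            raise ValueError("disturbance window outside the time series")


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment."""

    taxa: pd.DataFrame          # index taxon_id: trf_bp, lineage
    abundance: pd.DataFrame     # index sample_id, columns taxon ids, %
    covariates: pd.DataFrame    # index sample_id: reactor, timepoint, VFA/CH4/CO2
    disturbed_taxa: list[str] = field(default_factory=list)
    window: tuple[int, int] = (0, 0)


def _lineage_for(i: int) -> Lineage:
    domain = "Bacteria"
    phylum, class_, order, family = _PHYLA[i % len(_PHYLA)]
    genus = f"Synthetigenus{i + 1:02d}"
    species = f"{genus} fictus"
    return Lineage(domain, phylum, class_, order, family, genus, species)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _concrete_site(rng: np.random.Generator, enzyme: Enzyme) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in enzyme.site)


def planted_trf_sizes(config: SimConfig) -> list[int]:
    """Deterministic choice of the planted fragment sizes: even integers on
    a grid with spacing >= trf_min_gap inside trf_range."""
    rng = np.random.default_rng([config.seed, 10])
    step = max(2, config.trf_min_gap + (config.trf_min_gap % 2))
    lo = config.trf_range[0] + (config.trf_range[0] % 2)
    candidates = list(range(lo, config.trf_range[1] + 1, step))
    if len(candidates) < config.n_taxa:
        raise ValueError(
            f"cannot place {config.n_taxa} fragment sizes with spacing {step} "
            f"inside {config.trf_range}"
        )
    chosen = rng.choice(len(candidates), size=config.n_taxa, replace=False)
    return sorted(candidates[i] for i in chosen)


def gen_reference_db(
    config: SimConfig,
    *,
    fwd: Primer = DEFAULT_FWD_PRIMER,
    rev: Primer = DEFAULT_REV_PRIMER,
) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Generate reference amplicons with exactly one guaranteed enzyme site
    each, placed so the tagged terminal fragment equals the planted size.

    Accidental guaranteed sites upstream of the planted one (including
    sites straddling the primer junctions) are removed by bounded
    mutate-and-rescan repair; failure after the retry budget is an error.
    Returns the records and a truth frame (taxon id -> planted TRF,
    lineage string).
    """
    enzyme = get_enzyme(config.enzyme)
    rng = np.random.default_rng([config.seed, 11])
    trfs = planted_trf_sizes(config)
    site_len = len(enzyme.site)
    fwd_len = len(fwd.seq)

    records: list[ReferenceRecord] = []
    rows = []
    for i, trf in enumerate(trfs):
        taxon_id = f"SYN{i + 1:04d}"
        p = trf - fwd_len - enzyme.cut_offset  # site start inside the insert
        if p < 0:
            raise ValueError(f"planted TRF {trf} too small for the primer tag")
        lo = max(p + site_len + 10, config.insert_len_range[0])
        hi = max(lo + 1, config.insert_len_range[1])
        insert_len = int(rng.integers(lo, hi + 1))
        placed = False
        for _attempt in range(60):
            ins = _random_bases(rng, insert_len, config.gc)
            ins[p: p + site_len] = list(_concrete_site(rng, enzyme))
            seq = "".join(ins)
            ok = True
            for _repair in range(200):
                tagged = tag_with_primers(seq, fwd, rev, record_id=taxon_id)
                sites = find_sites(tagged.seq, enzyme, "guaranteed")
                expected = fwd_len + p
                early = [s for s in sites if s < expected]
                if not early:
                    ok = expected in sites
                    break
                # mutate one insert base inside the first offending window
                window = range(early[0], early[0] + site_len)
                insert_positions = [
                    w - fwd_len
                    for w in window
                    if fwd_len <= w < fwd_len + insert_len
                    and not (p <= w - fwd_len < p + site_len)
                ]
                if not insert_positions:
                    ok = False
                    break
                j = int(rng.choice(insert_positions))
                pat_set = IUPAC_SETS[enzyme.site[j + fwd_len - early[0]]]
                options = sorted(set("ACGT") - pat_set) or sorted("ACGT")
                seq = seq[:j] + str(rng.choice(options)) + seq[j + 1:]
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a unique {enzyme.name} site for TRF {trf} "
                f"after bounded retries"
            )
        lineage = _lineage_for(i)
        records.append(ReferenceRecord(id=taxon_id, lineage=lineage, seq=seq))
        rows.append({"taxon_id": taxon_id, "trf_bp": trf,
                     "lineage": lineage.to_string()})
    truth = pd.DataFrame(rows).set_index("taxon_id")
    return records, truth


def write_reference(
    records: Sequence[ReferenceRecord], fasta_path, taxonomy_path
) -> None:
    """Write records as multi-FASTA plus the id/lineage TSV the reader expects."""
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i: i + 70] + "\n")
    pd.DataFrame(
        {"id": [r.id for r in records],
         "lineage": [r.lineage.to_string() for r in records]}
    ).to_csv(taxonomy_path, sep="\t", index=False)


def _disturbance_shape(t: int, window: tuple[int, int]) -> float:
    """Half-sine pulse over the disturbance window, 0 outside."""
    lo, hi = window
    if not lo <= t < hi or hi == lo:
        return 0.0
    return float(np.sin(np.pi * (t - lo + 0.5) / (hi - lo)))


def gen_community_series(
    config: SimConfig, taxa_truth: Optional[pd.DataFrame] = None
) -> TruthTable:
    """Two-reactor community time-series.

    The control reactor (GR2) holds Dirichlet-drawn proportions with small
    multiplicative drift; the disturbed reactor (GR1) multiplies the
    designated taxa by a log-scale half-sine fold-change pulse inside the
    disturbance window and renormalises.  Covariates mirror the pulse:
    volatile fatty acids and CO2 rise while CH4 falls.
    """
    if taxa_truth is None:
        _, taxa_truth = gen_reference_db(config)
    rng = np.random.default_rng([config.seed, 12])
    taxa = list(taxa_truth.index)
    n = len(taxa)
    base = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    disturbed = taxa[: config.n_disturbed_taxa]

    # the disturbed series is the control series plus fold changes, so the
    # per-timepoint drift is shared: with fold change 1 the reactors are
    # identical by construction.
    drifts = np.exp(rng.normal(0.0, config.drift_sd, size=(config.n_timepoints, n)))
    control = base * drifts  # unnormalised control proportions per timepoint

    ab_rows, cov_rows, index = [], [], []
    for reactor in ("GR1", "GR2"):
        for t in range(config.n_timepoints):
            prop = control[t].copy()
            shape = _disturbance_shape(t, config.disturbance_window)
            if reactor == "GR1" and shape > 0:
                fold = np.ones(n)
                fold[: config.n_disturbed_taxa] = config.peak_fold ** shape
                prop = prop * fold
            prop = 100.0 * prop / prop.sum()
            sample = f"{reactor}_t{t:02d}"
            index.append(sample)
            ab_rows.append(prop)
            if reactor == "GR1":
                vfa = 0.5 + 20.0 * shape + abs(rng.normal(0.0, 0.1))
                ch4 = 59.0 - 14.0 * shape + rng.normal(0.0, 0.5)
                co2 = 33.0 + 15.0 * shape + rng.normal(0.0, 0.5)
            else:
                vfa = 0.5 + abs(rng.normal(0.0, 0.1))
                ch4 = 59.0 + rng.normal(0.0, 0.5)
                co2 = 33.0 + rng.normal(0.0, 0.5)
            cov_rows.append(
                {"reactor": reactor, "timepoint": t,
                 "vfa_g_per_l": round(vfa, 3), "ch4_pct": round(ch4, 2),
                 "co2_pct": round(co2, 2)}
            )
    abundance = pd.DataFrame(ab_rows, index=index, columns=taxa)
    covariates = pd.DataFrame(cov_rows, index=index)
    abundance.index.name = covariates.index.name = "sample"
    return TruthTable(
        taxa=taxa_truth, abundance=abundance, covariates=covariates,
        disturbed_taxa=list(disturbed), window=config.disturbance_window,
    )


#: MapMarker-like internal size standard (orange channel), bp.
LADDER_SIZES = tuple(range(50, 1001, 50))


def simulate_electropherogram(
    truth: TruthTable, config: SimConfig, path: str | Path
) -> Path:
    """Write a Peak-Scanner-style CSV for every sample in ``truth``.

    Per sample: one blue-channel (FAM) peak per taxon with abundance > 0,
    at size Normal(planted TRF, jitter sd) and height proportional to
    abundance times a lognormal amplification factor; an orange-channel
    size-standard ladder; and Poisson-many uniform noise peaks whose
    heights stay below ``noise_ceiling * min_proportion`` of the sample's
    real signal, so the iterative noise filter removes them all.
    """
    rng = np.random.default_rng([config.seed, 13])
    trf_by_taxon = truth.taxa["trf_bp"].to_dict()
    rows = []
    for sample, ab in truth.abundance.iterrows():
        real_heights = []
        for taxon, pct in ab.items():
            if pct <= 0:
                continue
            size = float(trf_by_taxon[taxon]) + rng.normal(0.0, config.size_jitter_sd)
            height = (
                pct / 100.0 * config.total_signal
                * float(np.exp(rng.normal(0.0, config.amplification_sd)))
            )
            real_heights.append(height)
            rows.append(
                {"Sample File Name": sample, "Dye/Sample Peak": "B",
                 "Size": round(max(size, 1.0), 2), "Height": round(height, 1)}
            )
        total_real = sum(real_heights)
        cap = config.noise_ceiling * config.min_proportion * total_real
        n_noise = int(rng.poisson(config.noise_rate))
        for _ in range(n_noise):
            size = float(rng.uniform(40.0, 650.0))
            height = float(rng.uniform(0.05 * cap, max(cap, 0.1)))
            rows.append(
                {"Sample File Name": sample, "Dye/Sample Peak": "B",
                 "Size": round(size, 2), "Height": round(height, 1)}
            )
        for size in LADDER_SIZES:
            rows.append(
                {"Sample File Name": sample, "Dye/Sample Peak": "O",
                 "Size": float(size), "Height": 1200.0}
            )
    df = pd.DataFrame(rows, columns=["Sample File Name", "Dye/Sample Peak",
                                     "Size", "Height"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def simulate_experiment(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full fixture set on disk: reference FASTA + taxonomy,
    peak CSV, truth abundances and covariates.  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, taxa_truth = gen_reference_db(config)
    truth = gen_community_series(config, taxa_truth)
    paths = {
        "reference_fasta": out / "reference.fasta",
        "taxonomy_tsv": out / "taxonomy.tsv",
        "peaks_csv": out / "peaks.csv",
        "truth_abundance_tsv": out / "truth_abundance.tsv",
        "truth_taxa_tsv": out / "truth_taxa.tsv",
        "covariates_tsv": out / "covariates.tsv",
    }
    write_reference(records, paths["reference_fasta"], paths["taxonomy_tsv"])
    simulate_electropherogram(truth, config, paths["peaks_csv"])
    truth.abundance.to_csv(paths["truth_abundance_tsv"], sep="\t")
    truth.taxa.to_csv(paths["truth_taxa_tsv"], sep="\t")
    truth.covariates.to_csv(paths["covariates_tsv"], sep="\t")
    return paths
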