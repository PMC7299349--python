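"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one input of the analysis pipeline — diauxic
OD420 growth curves, competition colony counts, clone x gene mutation
tables, IS-insertion site draws, negative-binomial coverage with planted
amplifications, and per-cell fluorescence with a known death proportion
— returning in-memory objects plus a truth dictionary sufficient to
score any estimator. ``save_run`` writes the objects to the same file
formats the readers consume, alongside a TOML truth sidecar. All
generators are deterministic per seed.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import CoverageTrack
from .fitness import CompetitionAssay, PlateCount
from .growth import ODCurve
from .insertions import InsertionEvent, SiteCatalog
from .parallelism import GeneLink, MutationRecord
from .stats import rng_for
from .viability import CellRecord

__all__ = [
    "gen_od_curves",
    "gen_competition_counts",
    "gen_mutation_table",
    "gen_insertion_sites",
    "gen_coverage",
    "gen_cells",
    "save_run",
]


# ----------------------------------------------------------- growth curves


def gen_od_curves(
    r_glucose: Optional[float] = 0.8,
    r_citrate: float = 0.3,
    lag_h: float = 2.0,
    shift_od: float = 0.03,
    plateau_od: float = 0.5,
    baseline_od: float = 0.005,
    lag_threshold: float = 0.01,
    noise_sd: float = 0.02,
    n_wells: int = 6,
    dt_min: float = 10.0,
    horizon_h: float = 48.0,
    sample_id: str = "synthetic",
    seed: int = 0,
) -> tuple[list[ODCurve], dict]:
    """Diauxic (or single-phase) OD420 curves with known kinetics.

    The deterministic trajectory sits at ``baseline_od``, grows
    exponentially at ``r_glucose`` through the lag-threshold crossing at
    exactly ``lag_h`` up to the diauxic shift at ``shift_od``, then at
    ``r_citrate`` up to ``plateau_od``. Passing ``r_glucose=None``
    produces citrate-only (DM0-style) single-phase curves growing at
    ``r_citrate``. Noise is multiplicative lognormal with log-sd
    ``noise_sd`` (plate readers show proportional error).
    """
    medium = "DM0" if r_glucose is None else "DM25"
    r1 = r_citrate if r_glucose is None else r_glucose
    t = np.arange(0.0, horizon_h + 1e-9, dt_min / 60.0)

    od = lag_threshold * np.exp(r1 * (t - lag_h))
    od = np.maximum(od, baseline_od)
    if r_glucose is not None:
        t_shift = lag_h + math.log(shift_od / lag_threshold) / r_glucose
        late = t >= t_shift
        od[late] = shift_od * np.exp(r_citrate * (t[late] - t_shift))
    od = np.minimum(od, plateau_od)

    rng = rng_for(seed, "od-curves")
    curves = []
    for w in range(n_wells):
        noisy = od * np.exp(rng.normal(0.0, noise_sd, size=od.size)) if noise_sd > 0 else od
        curves.append(
            ODCurve(
                sample_id=sample_id,
                well_id=f"W{w + 1:02d}",
                medium=medium,
                times=t.copy(),
                od=noisy,
            )
        )
    truth = {
        "generator": "gen_od_curves",
        "seed": seed,
        "medium": medium,
        "r_glucose": float("nan") if r_glucose is None else r_glucose,
        "r_citrate": r_citrate,
        "lag_h": lag_h,
        "shift_od": shift_od,
        "plateau_od": plateau_od,
        "noise_sd": noise_sd,
        "n_wells": n_wells,
    }
    return curves, truth


# ------------------------------------------------------ competition counts


def gen_competition_counts(
    true_W: float = 1.28,
    n0_each: float = 5e5,
    m_ref_per_day: float = math.log(100.0),
    duration_days: int = 1,
    transfer_dilution: float = 100.0,
    initial_dilutions: Sequence[float] = (1e2, 1e3),
    final_dilutions: Sequence[float] = (1e4, 1e5),
    volume_ml: float = 0.1,
    n_replicates: int = 6,
    poisson: bool = True,
    seed: int = 0,
) -> tuple[list[CompetitionAssay], dict]:
    """Competition assays with a known true relative fitness.

    Densities follow the Malthusian model with
    ``m_test = true_W * m_ref`` per day; colony counts on each dilution
    plate are Poisson(density x volume / dilution) unless ``poisson``
    is disabled (then rounded expectations, for exact round trips).
    """
    if true_W <= 0:
        raise ValueError("true_W must be positive")
    rng = rng_for(seed, "competition-counts")
    m_ref = m_ref_per_day * duration_days
    m_test = true_W * m_ref
    final_density = {
        "test": n0_each * math.exp(m_test) / transfer_dilution ** (duration_days - 1),
        "reference": n0_each * math.exp(m_ref) / transfer_dilution ** (duration_days - 1),
    }

    def plates(role: str, density: float, dilutions: Sequence[float]) -> list[PlateCount]:
        out = []
        for dil in dilutions:
            lam = density * volume_ml / dil
            colonies = int(rng.poisson(lam)) if poisson else int(round(lam))
            out.append(
                PlateCount(
                    competitor_id=f"{role}-strain",
                    marker="Ara+" if role == "test" else "Ara-",
                    dilution_factor=dil,
                    volume_ml=volume_ml,
                    colonies=colonies,
                )
            )
        return out

    assays = []
    for rep in range(n_replicates):
        assays.append(
            CompetitionAssay(
                replicate_id=f"R{rep + 1}",
                duration_days=duration_days,
                transfer_dilution=transfer_dilution,
                initial={
                    role: plates(role, n0_each, initial_dilutions)
                    for role in ("test", "reference")
                },
                final={
                    role: plates(role, final_density[role], final_dilutions)
                    for role in ("test", "reference")
                },
            )
        )
    truth = {
        "generator": "gen_competition_counts",
        "seed": seed,
        "true_W": true_W,
        "n0_each": n0_each,
        "m_ref_per_day": m_ref_per_day,
        "duration_days": duration_days,
        "transfer_dilution": transfer_dilution,
        "n_replicates": n_replicates,
        "poisson": poisson,
    }
    return assays, truth


# -------------------------------------------------------- mutation tables


def gen_mutation_table(
    n_clones_per_treatment: int = 12,
    gene_universe_size: int = 50,
    target_genes: Optional[dict[str, dict[str, float]]] = None,
    background_rate: float = 0.05,
    type_mixture: Optional[dict[str, float]] = None,
    nonqualifying_per_clone: int = 2,
    genome_length: int = 4_600_000,
    seed: int = 0,
) -> tuple[list[MutationRecord], dict]:
    """Clone x gene mutation tables with treatment-specific hit probabilities.

    Every clone hits every gene independently (Bernoulli): targeted
    genes with their per-treatment probability, all others at
    ``background_rate``. Hits get a qualifying type drawn from
    ``type_mixture`` and a single coding gene link. Each clone also
    receives ``nonqualifying_per_clone`` decoy records (synonymous SNPs,
    a two-gene deletion, an ambiguous intergenic SNP in rotation) so the
    qualifying filter is exercised.
    """
    if target_genes is None:
        target_genes = {"DM0": {}, "DM25": {}}
    if type_mixture is None:
        type_mixture = {"snp_nonsynonymous": 0.4, "is_insertion": 0.4, "deletion": 0.2}
    types = sorted(type_mixture)
    type_p = np.array([type_mixture[t] for t in types], dtype=float)
    type_p = type_p / type_p.sum()
    genes = [f"gene{i + 1:04d}" for i in range(gene_universe_size)]
    rng = rng_for(seed, "mutation-table")

    records: list[MutationRecord] = []
    clones: list[tuple[str, str]] = []
    for treatment in ("DM0", "DM25"):
        targets = target_genes.get(treatment, {})
        for c in range(n_clones_per_treatment):
            clone_id = f"{treatment}-c{c + 1:02d}"
            clones.append((clone_id, treatment))
            if not genes:
                continue
            for gi, gene in enumerate(genes):
                p = targets.get(gene, background_rate)
                if rng.random() >= p:
                    continue
                mtype = types[rng.choice(len(types), p=type_p)]
                records.append(
                    MutationRecord(
                        clone_id=clone_id,
                        treatment=treatment,
                        position=int(rng.integers(1, genome_length)),
                        type=mtype,
                        element="IS150" if mtype == "is_insertion" else "",
                        genes_affected=(GeneLink(gene=gene, relation="coding"),),
                    )
                )
            for j in range(nonqualifying_per_clone):
                pos = int(rng.integers(1, genome_length))
                kind = j % 3
                if kind == 0:  # synonymous SNP: wrong type
                    records.append(
                        MutationRecord(
                            clone_id=clone_id, treatment=treatment, position=pos,
                            type="snp_synonymous",
                            genes_affected=(GeneLink(genes[0], "coding"),),
                        )
                    )
                elif kind == 1:  # two-gene deletion: ambiguous
                    records.append(
                        MutationRecord(
                            clone_id=clone_id, treatment=treatment, position=pos,
                            type="deletion",
                            genes_affected=(
                                GeneLink(genes[0], "coding"),
                                GeneLink(genes[1 % len(genes)], "coding"),
                            ),
                        )
                    )
                else:  # intergenic SNP with two promoter candidates
                    records.append(
                        MutationRecord(
                            clone_id=clone_id, treatment=treatment, position=pos,
                            type="snp_intergenic",
                            genes_affected=(
                                GeneLink(genes[0], "promoter", 40),
                                GeneLink(genes[1 % len(genes)], "promoter", 60),
                            ),
                        )
                    )
    truth = {
        "generator": "gen_mutation_table",
        "seed": seed,
        "n_clones_per_treatment": n_clones_per_treatment,
        "gene_universe_size": gene_universe_size,
        "background_rate": background_rate,
        "target_genes": {t: dict(g) for t, g in target_genes.items()},
        "clones": [f"{cid}:{trt}" for cid, trt in clones],
    }
    return records, truth


# -------------------------------------------------------- insertion sites


def gen_insertion_sites(
    weights: Sequence[int] = (8, 5, 3, 2, 2, 1, 1, 1, 1, 1),
    hotspot_index: int = 0,
    hotspot_factor: float = 1.0,
    n_insertions_per_group: Optional[dict[str, int]] = None,
    n_clones_per_group: int = 12,
    element: str = "IS150",
    seed: int = 0,
) -> tuple[list[InsertionEvent], SiteCatalog, dict]:
    """Multinomial insertion-site draws against a weighted site catalog.

    The null catalog has the given weights at sites 1000, 2000, ...;
    true insertion probabilities are proportional to the weights with
    ``hotspot_factor`` multiplying the weight of one site
    (factor 1 reproduces the null exactly). Each group's total insertion
    count is fixed and the drawn insertions are distributed round-robin
    over the group's clones.
    """
    if n_insertions_per_group is None:
        n_insertions_per_group = {"DM0": 102, "DM25": 60}
    sites = tuple(1000 * (i + 1) for i in range(len(weights)))
    catalog = SiteCatalog(sites=sites, weights=tuple(int(w) for w in weights))
    true_w = np.asarray(weights, dtype=float)
    true_w[hotspot_index] *= hotspot_factor
    probs = true_w / true_w.sum()
    rng = rng_for(seed, "insertion-sites")

    events: list[InsertionEvent] = []
    for treatment, n_ins in sorted(n_insertions_per_group.items()):
        counts = rng.multinomial(n_ins, probs)
        flat = np.repeat(np.arange(len(sites)), counts)
        rng.shuffle(flat)
        for k, site_idx in enumerate(flat):
            clone = f"{treatment}-c{(k % n_clones_per_group) + 1:02d}"
            events.append(
                InsertionEvent(
                    clone_id=clone,
                    treatment=treatment,
                    element=element,
                    site=sites[site_idx],
                    gene_label=f"gene{site_idx + 1:04d}",
                    relation="coding",
                )
            )
    truth = {
        "generator": "gen_insertion_sites",
        "seed": seed,
        "sites": list(sites),
        "catalog_weights": [int(w) for w in weights],
        "hotspot_index": hotspot_index,
        "hotspot_factor": hotspot_factor,
        "hotspot_site": sites[hotspot_index],
        "n_insertions_per_group": dict(n_insertions_per_group),
    }
    return events, catalog, truth


# -------------------------------------------------------------- coverage


def gen_coverage(
    genome_length: int = 100_000,
    mu: float = 50.0,
    size: float = 10.0,
    planted_regions: Sequence[tuple[int, int, float]] = (),
    genome_id: str = "synthetic",
    seed: int = 0,
) -> tuple[CoverageTrack, dict]:
    """Negative-binomial coverage with planted amplified segments.

    Depth at each position is NB(mu x copy, size) with copy = 1 outside
    the planted (start, end, copy_number) regions (1-based inclusive).
    Positions are generated independently; read-level autocorrelation is
    not modelled.
    """
    copy = np.ones(genome_length)
    for start, end, cn in planted_regions:
        if not (1 <= start <= end <= genome_length):
            raise ValueError("planted region outside genome")
        copy[start - 1 : end] = cn
    rng = rng_for(seed, "coverage")
    mean = mu * copy
    p = size / (size + mean)
    depth = rng.negative_binomial(size, p)
    truth = {
        "generator": "gen_coverage",
        "seed": seed,
        "genome_length": genome_length,
        "mu": mu,
        "size": size,
        "planted_regions": [list(map(float, r)) for r in planted_regions],
    }
    return CoverageTrack(genome_id=genome_id, depth=depth), truth


# ------------------------------------------------------------------ cells


def gen_cells(
    n_replicates: int = 5,
    cells_per_replicate: int = 2000,
    true_death_proportion: float = 0.30,
    live_green: tuple[float, float] = (200.0, 20.0),
    live_red: tuple[float, float] = (50.0, 10.0),
    dead_green: tuple[float, float] = (50.0, 10.0),
    dead_red: tuple[float, float] = (200.0, 20.0),
    noncell_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[CellRecord], dict]:
    """Per-cell fluorescence records with a known death proportion.

    Channel intensities are normal (clipped at 0) with well-separated
    live/dead means by default. Real cells get region scores uniform on
    [25, 50]; an extra ``noncell_fraction`` of records (relative to the
    cell count) get scores uniform on [-50, 25) and random channels, so
    the region-score filter is exercised.
    """
    if not 0.0 <= true_death_proportion <= 1.0:
        raise ValueError("true_death_proportion must lie in [0, 1]")
    rng = rng_for(seed, "cells")
    cells: list[CellRecord] = []
    for r in range(n_replicates):
        rep = f"rep{r + 1}"
        dead = rng.random(cells_per_replicate) < true_death_proportion
        for is_dead in dead:
            g_mu, g_sd = dead_green if is_dead else live_green
            r_mu, r_sd = dead_red if is_dead else live_red
            cells.append(
                CellRecord(
                    replicate_id=rep,
                    region_score=float(rng.uniform(25.0, 50.0)),
                    green=max(0.0, float(rng.normal(g_mu, g_sd))),
                    red=max(0.0, float(rng.normal(r_mu, r_sd))),
                )
            )
        n_junk = int(round(noncell_fraction * cells_per_replicate))
        for _ in range(n_junk):
            cells.append(
                CellRecord(
                    replicate_id=rep,
                    region_score=float(rng.uniform(-50.0, 24.999)),
                    green=max(0.0, float(rng.normal(100.0, 50.0))),
                    red=max(0.0, float(rng.normal(100.0, 50.0))),
                )
            )
    truth = {
        "generator": "gen_cells",
        "seed": seed,
        "n_replicates": n_replicates,
        "cells_per_replicate": cells_per_replicate,
        "true_death_proportion": true_death_proportion,
        "noncell_fraction": noncell_fraction,
    }
    return cells, truth


# --------------------------------------------------------------- run output


def save_run(outdir: str | Path, truth: dict, **artifacts) -> Path:
    """Write generated artifacts and the TOML truth sidecar to a directory.

    Recognized keyword artifacts: ``curves`` (OD CSV), ``assays``
    (counts CSV), ``mutations`` (TSV), ``events``/``catalog`` (TSVs),
    ``track`` (bedGraph), ``cells`` (TSV).
    """
    from . import io as cio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if "curves" in artifacts:
        cio.write_od_csv(artifacts["curves"], out / "od_curves.csv")
    if "assays" in artifacts:
        rows = []
        for a in artifacts["assays"]:
            for timepoint, point in (("initial", a.initial), ("final", a.final)):
                for role, counts in sorted(point.items()):
                    for c in counts:
                        rows.append(
                            {
                                "replicate_id": a.replicate_id,
                                "competitor_id": c.competitor_id,
                                "role": role,
                                "timepoint": timepoint,
                                "dilution_factor": c.dilution_factor,
                                "volume_ml": c.volume_ml,
                                "colonies": c.colonies,
                            }
                        )
        cio.write_counts_csv(pd.DataFrame(rows), out / "counts.csv")
    if "mutations" in artifacts:
        cio.write_mutations_tsv(artifacts["mutations"], out / "mutations.tsv")
    if "events" in artifacts:
        cio.write_insertions_tsv(artifacts["events"], out / "insertions.tsv")
    if "catalog" in artifacts:
        cio.write_catalog_tsv(artifacts["catalog"], out / "catalog.tsv")
    if "track" in artifacts:
        cio.write_bedgraph(artifacts["track"], out / "coverage.bedgraph")
    if "cells" in artifacts:
        cio.write_cells_tsv(artifacts["cells"], out / "cells.tsv")
    cio.dump_toml(truth, out / "truth.toml")
    return out
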