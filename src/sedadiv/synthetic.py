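"""Synthetic multi-lake sedaDNA metabarcoding dataset generator.

Generates fixtures with the statistical structure the analysis assumes:
a regional taxon pool that accumulates through the Holocene at piecewise
colonization rates, per-lake sample series whose expected log richness
responds to a warming proxy and to a catchment nutrient index,
heterogeneous per-replicate sequencing depth with abundance-dependent
dropout, contaminant and unidentifiable sequences, blacklist false
positives, and negative controls with sporadic low-level detections.

Defaults mirror the emulated study design: 10 lakes (two of them short,
Late-Holocene-only records), 12-55 samples per lake, 8 PCR replicates
per sample, a 288-taxon regional pool accumulating at 42.37, 9.35 and
21.82 taxa per millennium in successive Holocene phases before levelling
off, and a temperature effect of 0.24 on log richness confined to the
Early Holocene.

Simulated reads are *not* sequencing reads: the generator emits
dereplicated per-replicate retained-read counts, the point where the
analysis pipeline starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sedadiv.drivers import nutrient_index, split_periods
from sedadiv.reference import ReferenceDatabase

DNA = np.array(list("ACGT"))

# colonization windows: (old age BP, young age BP, taxa per millennium)
DEFAULT_RATE_CURVE = (
    (11_700, 7_000, 42.37),
    (7_000, 5_000, 9.35),
    (5_000, 3_300, 21.82),
    (3_300, 0, 4.85),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design (defaults = study conditions)."""

    n_lakes: int = 10
    samples_per_lake: tuple = (12, 55)
    n_replicates: int = 8
    age_range: tuple = (11_700, 0)
    pool_size: int = 288
    n_initial_taxa: int = 17
    colonization_rate_curve: tuple = DEFAULT_RATE_CURVE
    beta_temperature: float = 0.24
    temperature_effect_periods: tuple = ("Early",)
    beta_nutrient: float = 0.12
    richness_intercept: float = 3.55      # log(35) baseline richness
    smooth_amplitude: float = 0.1
    d18o_reference: float = -35.5         # centering constants for effects
    ni_reference: float = 5.0
    depth_lognormal_params: tuple = (9.0, 1.0)
    inhibited_rate: float = 0.15
    inhibition_depth_factor: tuple = (0.001, 0.02)
    dropout_halfsat: float = 8.0
    abundance_sigma: float = 1.2
    contaminant_rate: float = 2.0
    false_positive_rate: float = 1.0
    aquatic_rate: float = 1.5
    negative_control_rate: float = 3.0
    n_short_lakes: int = 2
    n_ref_taxa: int = 380
    frac_aquatic: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if min(self.n_lakes, self.pool_size, self.n_ref_taxa,
               *self.samples_per_lake) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 PCR replicates")
        old, young = self.age_range
        if not old > young >= 0:
            raise ValueError("age_range must be ordered old -> young")
        if split_periods([old])[0] == split_periods([young])[0]:
            raise ValueError("age_range must span at least two Holocene periods")
        for w_old, w_young, rate in self.colonization_rate_curve:
            if rate < 0:
                raise ValueError("colonization rates must be non-negative")
        covered_old = max(w[0] for w in self.colonization_rate_curve)
        covered_young = min(w[1] for w in self.colonization_rate_curve)
        if covered_old < old or covered_young > young:
            raise ValueError("colonization rate curve does not cover age_range")


@dataclass
class LakeSpec:
    """One simulated lake and its catchment geology."""

    lake_id: str
    basal_age: int
    top_age: int
    n_samples: int
    P: float
    K: float
    Ca: float
    H_min: float

    @property
    def ni(self) -> float:
        return nutrient_index(self.P, self.K, self.Ca, self.H_min)


@dataclass
class TrueCommunity:
    """Ground-truth community of one sample."""

    sample_id: str
    lake_id: str
    age: int
    taxa: np.ndarray               # taxon names
    relative_abundances: np.ndarray

    def __post_init__(self):
        a = self.relative_abundances
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be a simplex vector")


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

def _random_seq(rng, lo=10, hi=80) -> str:
    return "".join(rng.choice(DNA, size=rng.integers(lo, hi + 1)))


def _unique_seq(rng, taken, lo=10, hi=80, max_retries=100) -> str:
    for _ in range(max_retries):
        s = _random_seq(rng, lo, hi)
        if s not in taken:
            taken.add(s)
            return s
    raise RuntimeError("could not generate a unique barcode after max retries")


def generate_reference_db(n_taxa: int, frac_aquatic: float = 0.1, seed: int = 0) -> ReferenceDatabase:
    """Emulated local barcode reference database.

    Produces ``n_taxa`` taxa with unique 10-80 nt barcodes, ranks drawn
    from species/genus/family/above-family, an aquatic + algal fraction,
    one *Vaccinium*-like pair differing only in 3' poly-A length, and a
    handful of taxa carrying two distinct barcodes (to exercise barcode
    merging).  Deterministic for a given seed.
    """
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    if not 0 <= frac_aquatic < 1:
        raise ValueError("frac_aquatic must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taken: set = set()
    rows = []

    # Vaccinium-like poly-A pair: same stem, different terminal run
    stem = _unique_seq(rng, taken, lo=20, hi=40)
    stem = stem.rstrip("A") + "C"       # guarantee the stem itself ends non-A
    taken.add(stem + "A" * 4)
    taken.add(stem + "A" * 10)
    rows.append(("Vaccinium myrtillus", "species", "terrestrial", stem + "A" * 4, True))
    rows.append(("Vaccinium vitis-idaea", "species", "terrestrial", stem + "A" * 10, True))

    n_rest = n_taxa - 2
    n_aq = int(round(n_taxa * frac_aquatic))
    n_alga = n_aq // 2
    groups = ["alga"] * n_alga + ["aquatic"] * (n_aq - n_alga) + ["terrestrial"] * (n_rest - n_aq)
    ranks = rng.choice(["species", "genus", "family", "above-family"],
                       size=n_rest, p=[0.5, 0.25, 0.17, 0.08])
    for i in range(n_rest):
        rows.append((f"Taxon{i:04d}", ranks[i], groups[i], _unique_seq(rng, taken), False))

    # give a few family-or-below terrestrial taxa a second barcode
    eligible = [r for r in rows if r[2] == "terrestrial" and r[1] != "above-family"
                and not r[4]]
    n_multi = max(2, int(round(0.05 * n_taxa)))
    for r in [eligible[i] for i in rng.choice(len(eligible), size=min(n_multi, len(eligible)),
                                              replace=False)]:
        rows.append((r[0], r[1], r[2], _unique_seq(rng, taken), False))

    tax = pd.DataFrame(rows, columns=["taxon", "rank", "group", "dna", "polya_group"])
    tax["barcode_id"] = [f"bc{i:04d}" for i in range(len(tax))]
    tax = tax.set_index("dna")[["barcode_id", "taxon", "rank", "group", "polya_group"]]
    return ReferenceDatabase(taxonomy=tax)


# ---------------------------------------------------------------------------
# climate proxy and lakes
# ---------------------------------------------------------------------------

def generate_proxy_series(age_range=(11_700, 0), resolution: int = 50, seed: int = 0) -> pd.DataFrame:
    """Synthetic Greenland-style delta-18-O series at fixed resolution.

    Piecewise trend emulating the Holocene: a steep Early-Holocene
    warming (+0.92 per ka), a flat Middle Holocene, and a slight Late
    Holocene cooling (-0.13 per ka), with AR(1) noise.  The two oldest
    grid points carry a brief cold oscillation below -39 so that the
    cold-outlier exclusion rule has something to exclude.
    """
    rng = np.random.default_rng(seed)
    old, young = age_range
    ages = np.arange(young, old + resolution, resolution)[::-1]  # old -> young grid
    ka = ages / 1000.0
    base = np.where(
        ka >= 8.3, -35.0 - 0.92 * (ka - 8.3),
        np.where(ka >= 4.25, -35.0, -35.0 - 0.13 * (4.25 - ka)),
    )
    noise = np.empty_like(base)
    noise[0] = rng.normal(0, 0.25)
    for i in range(1, len(noise)):
        noise[i] = 0.7 * noise[i - 1] + rng.normal(0, 0.18)
    d18o = base + noise
    if len(d18o) > 2 and old >= 11_000:
        d18o[:2] = np.minimum(d18o[:2], -39.3)
    return pd.DataFrame({"age": ages[::-1], "d18o": d18o[::-1]})  # ascending age


def generate_lakes(config: SimulationConfig) -> list:
    """Draw lake records and catchment geology (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    old, young = config.age_range
    lakes = []
    for i in range(config.n_lakes):
        short = i >= config.n_lakes - config.n_short_lakes and config.n_lakes >= 4
        if short:
            basal = int(rng.integers(3000, min(4200, old)))
        else:
            basal = int(rng.integers(max(young + 1000, int(old * 0.92)), old + 1))
        top = int(rng.integers(young, young + 300))
        n_samp = int(rng.integers(config.samples_per_lake[0], config.samples_per_lake[1] + 1))
        if short:
            n_samp = max(config.samples_per_lake[0], n_samp // 2)
        lakes.append(LakeSpec(
            lake_id=f"lake_{i:02d}",
            basal_age=basal, top_age=min(top, basal - 500), n_samples=n_samp,
            P=float(rng.uniform(2, 12)), K=float(rng.uniform(3, 15)),
            Ca=float(10 ** rng.uniform(1.7, 3.7)), H_min=float(rng.uniform(2.5, 7.0)),
        ))
    return lakes


# ---------------------------------------------------------------------------
# colonization and communities
# ---------------------------------------------------------------------------

def simulate_regional_colonization(config: SimulationConfig) -> dict:
    """Taxon index -> colonization age (cal yr BP), oldest first.

    Each rate window contributes round(rate * duration) colonizations at
    ages uniform within the window; ``n_initial_taxa`` are present from
    the start.  Raises if the configured pool cannot hold them all.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    old, young = config.age_range
    ages = [float(old)] * config.n_initial_taxa
    for w_old, w_young, rate in config.colonization_rate_curve:
        lo, hi = max(w_young, young), min(w_old, old)
        if hi <= lo:
            continue
        n_w = int(round(rate * (hi - lo) / 1000.0))
        ages.extend(rng.uniform(lo, hi, size=n_w))
    if len(ages) > config.pool_size:
        raise ValueError(
            f"pool_size {config.pool_size} smaller than implied colonizations {len(ages)}"
        )
    ages = sorted(ages, reverse=True)
    return {i: float(a) for i, a in enumerate(ages)}


def _expected_log_richness(age, d18o, ni, config: SimulationConfig):
    period = split_periods([age])[0]
    eta = config.richness_intercept
    if period in config.temperature_effect_periods:
        eta += config.beta_temperature * (d18o - config.d18o_reference)
    eta += config.beta_nutrient * (ni - config.ni_reference)
    t = (config.age_range[0] - age) / 1000.0
    eta += config.smooth_amplitude * np.sin(2 * np.pi * t / 8.0)
    return eta


def simulate_lake_record(
    lake: LakeSpec,
    colonization: dict,
    proxy: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pool_taxa: np.ndarray | None = None,
) -> list:
    """Simulate the true community series of one lake.

    Expected log richness is intercept + temperature effect (in the
    configured periods) + nutrient effect + a gentle smooth of age;
    realized richness is Poisson around it, truncated to the taxa already
    colonized at the sample's age.  Member taxa are drawn with
    lake-specific long-term affinities (log-normal weights, fixed per
    lake) and abundances are log-normal renormalized to the simplex.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    if pool_taxa is None:
        pool_taxa = np.array([f"pool{i:04d}" for i in range(config.pool_size)])
    col_ages = np.array([colonization.get(i, -np.inf) for i in range(len(pool_taxa))])

    grid = proxy.sort_values("age")
    gages = grid["age"].to_numpy(dtype=float)
    gvals = grid["d18o"].to_numpy(dtype=float)

    ages = np.linspace(lake.basal_age, lake.top_age, lake.n_samples)
    ages = np.round(ages + rng.uniform(-0.25, 0.25, lake.n_samples)
                    * np.diff(ages).mean()).astype(int)
    ages = np.clip(ages, config.age_range[1], config.age_range[0])
    ages = np.sort(ages)[::-1]

    affinity = rng.lognormal(0.0, 1.0, size=len(pool_taxa))
    communities = []
    for j, age in enumerate(ages):
        d18o = float(gvals[np.argmin(np.abs(gages - age))])
        eta = _expected_log_richness(age, d18o, lake.ni, config)
        colonized = np.flatnonzero(col_ages >= age)
        if np.exp(eta) > len(colonized):
            warnings.warn(f"{lake.lake_id}: expected richness exceeds colonized pool; clamped")
        R = int(np.clip(rng.poisson(np.exp(eta)), 1, len(colonized)))
        w = affinity[colonized]
        members = rng.choice(colonized, size=R, replace=False, p=w / w.sum())
        ab = rng.lognormal(0.0, config.abundance_sigma, size=R)
        communities.append(TrueCommunity(
            sample_id=f"{lake.lake_id}_s{j:03d}",
            lake_id=lake.lake_id,
            age=int(age),
            taxa=pool_taxa[np.sort(members)],
            relative_abundances=(lambda v: v / v.sum())(
                ab[np.argsort(members)]),
        ))
    return communities


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

class _SeqRegistry:
    """Stable ids for novel (non-reference) sequences within one dataset."""

    def __init__(self, refdb: ReferenceDatabase):
        self.known = {dna: row["barcode_id"] for dna, row in refdb.taxonomy.iterrows()}
        self.novel: dict = {}

    def id_of(self, dna: str) -> str:
        if dna in self.known:
            return self.known[dna]
        if dna not in self.novel:
            self.novel[dna] = f"nov{len(self.novel):05d}"
        return self.novel[dna]


def _taxon_barcodes(refdb: ReferenceDatabase) -> dict:
    out: dict = {}
    for dna, row in refdb.taxonomy.iterrows():
        out.setdefault(row["taxon"], []).append(dna)
    return out


def simulate_reads(
    community: TrueCommunity,
    refdb: ReferenceDatabase,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: _SeqRegistry | None = None,
    _barcodes: dict | None = None,
) -> pd.DataFrame:
    """Per-replicate dereplicated read counts for one sample.

    Replicate depths are log-normal; a taxon's detection probability per
    replicate saturates with (abundance x depth) around
    ``dropout_halfsat`` reads, and detected taxa get >=1 Poisson reads.
    Taxa with two reference barcodes emit both (70/30 split).  Off-target
    aquatic/unrankable reference sequences, novel contaminants and
    blacklisted false positives are injected at configured rates.
    """
    if registry is None:
        registry = _SeqRegistry(refdb)
    if _barcodes is None:
        _barcodes = _taxon_barcodes(refdb)
    n_rep = config.n_replicates
    mu, sigma = config.depth_lognormal_params
    depths = rng.lognormal(mu, sigma, size=n_rep)
    # occasional inhibited/ultralow-template samples: amplification collapses
    # across replicates, producing the sporadic top-10 replication that the
    # MTQ/MAQ gate is designed to catch
    if rng.random() < config.inhibited_rate:
        depths = depths * rng.uniform(*config.inhibition_depth_factor)

    counts: dict = {}

    def add(dna, rep, reads):
        if reads > 0:
            row = counts.setdefault(dna, np.zeros(n_rep, dtype=np.int64))
            row[rep] += reads

    for taxon, a in zip(community.taxa, community.relative_abundances):
        bcs = _barcodes.get(taxon, [])
        if not bcs:
            continue
        for r in range(n_rep):
            lam = a * depths[r]
            p = lam / (lam + config.dropout_halfsat) if config.dropout_halfsat > 0 else 1.0
            if rng.random() < p:
                reads = 1 + rng.poisson(lam)
                if len(bcs) > 1:
                    first = rng.binomial(reads, 0.7)
                    add(bcs[0], r, first)
                    add(bcs[1], r, reads - first)
                else:
                    add(bcs[0], r, reads)

    # off-target but identifiable sequences (aquatics, algae, above-family)
    off = refdb.taxonomy[(refdb.taxonomy["group"] != "terrestrial")
                         | (refdb.taxonomy["rank"] == "above-family")]
    for _ in range(rng.poisson(config.aquatic_rate)):
        if len(off) == 0:
            break
        dna = off.index[rng.integers(len(off))]
        for r in rng.choice(n_rep, size=rng.integers(2, min(6, n_rep + 1)), replace=False):
            add(dna, r, int(rng.integers(3, 60)))

    # novel contaminants, absent from the reference database
    for _ in range(rng.poisson(config.contaminant_rate)):
        dna = _random_seq(rng)
        while dna in refdb.taxonomy.index:
            dna = _random_seq(rng)
        n_hit = rng.integers(1, 3)
        for r in rng.choice(n_rep, size=n_hit, replace=False):
            add(dna, r, max(3, int(rng.lognormal(4.0, 1.5))))

    # blacklisted false positives
    fp = sorted(refdb.blacklist_false_positive)
    for _ in range(rng.poisson(config.false_positive_rate)):
        if not fp:
            break
        dna = fp[rng.integers(len(fp))]
        for r in rng.choice(n_rep, size=rng.integers(1, 4), replace=False):
            add(dna, r, int(rng.integers(3, 40)))

    return _rows_to_frame(counts, community.lake_id, community.sample_id,
                          "sample", registry, n_rep)


def simulate_negative_control(
    lake_id: str,
    control_id: str,
    refdb: ReferenceDatabase,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: _SeqRegistry | None = None,
) -> pd.DataFrame:
    """Sporadic low-level detections typical of extraction/PCR blanks."""
    if registry is None:
        registry = _SeqRegistry(refdb)
    n_rep = config.n_replicates
    counts: dict = {}
    ref_seqs = list(refdb.taxonomy.index)
    for _ in range(rng.poisson(config.negative_control_rate)):
        if rng.random() < 0.5 and ref_seqs:
            dna = ref_seqs[rng.integers(len(ref_seqs))]
        else:
            dna = _random_seq(rng)
        for r in rng.choice(n_rep, size=rng.integers(1, 3), replace=False):
            row = counts.setdefault(dna, np.zeros(n_rep, dtype=np.int64))
            row[r] += int(rng.integers(3, 40))
    return _rows_to_frame(counts, lake_id, control_id, "neg_control", registry, n_rep)


def _rows_to_frame(counts, lake_id, sample_id, sample_type, registry, n_rep):
    rows = []
    for dna in sorted(counts):
        rows.append({
            "lake_id": lake_id, "sample_id": sample_id, "sample_type": sample_type,
            "sequence_id": registry.id_of(dna), "dna": dna,
            **{f"rep_{r + 1}": int(counts[dna][r]) for r in range(n_rep)},
        })
    cols = ["lake_id", "sample_id", "sample_type", "sequence_id", "dna"] + \
        [f"rep_{r + 1}" for r in range(n_rep)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> dict:
    """Generate the full fixture: counts, reference, lakes, proxy, truth.

    Deterministic for a given config (including seed).  Returns a dict of
    DataFrames plus the :class:`ReferenceDatabase`.
    """
    ss = np.random.SeedSequence([config.seed, 1])
    seeds = ss.generate_state(4)
    refdb = generate_reference_db(config.n_ref_taxa, config.frac_aquatic,
                                  seed=int(seeds[0]))
    rng_bl = np.random.default_rng(int(seeds[1]))
    taken = set(refdb.taxonomy.index)
    bl_syn = frozenset(_unique_seq(rng_bl, taken) for _ in range(6))
    # false positives: novel homopolymer-variant-like sequences plus a few
    # reference barcodes (food-contaminant-like); a blacklisted sequence may
    # also sit in the reference database, and the blacklist wins
    off_seqs = refdb.taxonomy.index[
        (refdb.taxonomy["group"] != "terrestrial")
        | (refdb.taxonomy["rank"] == "above-family")
    ]
    n_ref_fp = min(4, len(off_seqs))
    ref_fp = list(off_seqs[rng_bl.choice(len(off_seqs), size=n_ref_fp, replace=False)])
    bl_fp = frozenset([_unique_seq(rng_bl, taken) for _ in range(8)] + ref_fp)
    refdb = ReferenceDatabase(refdb.taxonomy, blacklist_synthetic=bl_syn,
                              blacklist_false_positive=bl_fp)

    tax = refdb.taxonomy
    pool_candidates = (
        tax[(tax["group"] == "terrestrial") & (tax["rank"] != "above-family")]
        ["taxon"].drop_duplicates().sort_values().to_numpy()
    )
    if len(pool_candidates) < config.pool_size:
        raise ValueError(
            f"reference database provides {len(pool_candidates)} terrestrial "
            f"family-or-below taxa; pool_size={config.pool_size} requires more"
        )
    pool_taxa = pool_candidates[:config.pool_size]

    proxy = generate_proxy_series(config.age_range, seed=int(seeds[2]))
    lakes = generate_lakes(config)
    colonization = simulate_regional_colonization(config)

    registry = _SeqRegistry(refdb)
    barcodes = _taxon_barcodes(refdb)
    counts_frames, truth_rows = [], []
    for i, lake in enumerate(lakes):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100 + i]))
        communities = simulate_lake_record(lake, colonization, proxy, config,
                                           rng=rng, pool_taxa=pool_taxa)
        for com in communities:
            counts_frames.append(simulate_reads(com, refdb, config, rng,
                                                registry, barcodes))
            truth_rows.append({
                "lake_id": com.lake_id, "sample_id": com.sample_id, "age": com.age,
                "true_richness": len(com.taxa),
                "true_taxa": ";".join(com.taxa),
            })
        for c in range(max(1, lake.n_samples // 10)):
            counts_frames.append(simulate_negative_control(
                lake.lake_id, f"{lake.lake_id}_nc{c:02d}", refdb, config, rng,
                registry))

    counts = pd.concat([f for f in counts_frames if len(f)], ignore_index=True)
    lakes_df = pd.DataFrame([{
        "lake_id": lk.lake_id, "basal_age": lk.basal_age, "top_age": lk.top_age,
        "n_samples": lk.n_samples, "P": lk.P, "K": lk.K, "Ca": lk.Ca,
        "H_min": lk.H_min, "ni": lk.ni,
    } for lk in lakes])
    truth_samples = pd.DataFrame(truth_rows)
    truth_colonization = pd.DataFrame({
        "taxon": [pool_taxa[i] for i in sorted(colonization)],
        "colonization_age": [colonization[i] for i in sorted(colonization)],
    })
    ages = truth_samples.set_index(["lake_id", "sample_id"])["age"].astype(float)
    return {
        "counts": counts, "refdb": refdb, "lakes": lakes_df, "proxy": proxy,
        "truth_samples": truth_samples, "truth_colonization": truth_colonization,
        "ages": ages, "config": config,
    }


def write_fixture(dataset: dict, outdir: str | Path) -> None:
    """Write the fixture as plain-text TSV/FASTA files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    dataset["counts"].to_csv(out / "counts.tsv", sep="\t", index=False)
    dataset["refdb"].to_files(
        out / "reference.fasta", out / "taxonomy.tsv",
        out / "blacklist_synthetic.txt", out / "blacklist_false_positives.txt",
    )
    dataset["lakes"].to_csv(out / "lakes.tsv", sep="\t", index=False,
                            float_format=float_fmt)
    dataset["proxy"].to_csv(out / "proxy.tsv", sep="\t", index=False,
                            float_format=float_fmt)
    dataset["truth_samples"].to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    dataset["truth_colonization"].to_csv(out / "truth_colonization.tsv", sep="\t",
                                         index=False, float_format=float_fmt)
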