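"""Synthetic closed-line population generator.

Builds a multigenerational purebred-style pedigree, founder haplotypes with
tunable linkage disequilibrium, gene-dropped genotypes and genotype
missingness, so that every downstream analysis stage (QC, kinship, REML,
association scans, power study) can be exercised without external data.

The founder-LD mechanism is an ancestral-pool mosaic: a small pool of
``n_anc`` ancestral haplotypes is drawn, and each founder haplotype is a
mosaic of pool haplotypes with switch points placed by a Poisson process
along the genetic map. Short-range LD is controlled by the effective pool
size (unequal pool weights), long-range decay by the switch rate. Additional
LD accumulates by drift during the gene drop through the closed pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for a missing genotype call

#: Animals per generation (males, females) of the default seven-generation
#: closed line: 16/22, 19/40, 42/47, 67/86, 73/86, 71/86, 80/101 = 836 total.
DEFAULT_GENERATION_SIZES: tuple[tuple[int, int], ...] = (
    (16, 22),
    (19, 40),
    (42, 47),
    (67, 86),
    (73, 86),
    (71, 86),
    (80, 101),
)

UNKNOWN = "0"  # unknown-parent sentinel (PLINK convention)


def morgans(pos_bp: np.ndarray, cm_per_mb: float = 1.0) -> np.ndarray:
    """Physical bp -> genetic position in Morgan (default 1 Mb = 1 cM)."""
    return np.asarray(pos_bp, dtype=float) * cm_per_mb / 1e6 / 100.0


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Topologically ordered pedigree table.

    Columns: ``id, sire, dam, sex, generation``; unknown parents are ``"0"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def founder_mask(self) -> np.ndarray:
        t = self.table
        return ((t["sire"] == UNKNOWN) & (t["dam"] == UNKNOWN)).to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row index of sire/dam per animal (-1 = unknown)."""
        pos = {a: i for i, a in enumerate(self.table["id"])}
        sire = np.array([pos.get(s, -1) for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.table["dam"]], dtype=np.int64)
        return sire, dam

    def validate(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(t["id"])}
        gen = t["generation"].to_numpy()
        for i, (s, d) in enumerate(zip(t["sire"], t["dam"])):
            for p in (s, d):
                if p == UNKNOWN:
                    continue
                if p not in pos:
                    raise ValueError(f"unknown parent id {p!r}")
                j = pos[p]
                if j >= i:
                    raise ValueError("parent appears after offspring")
                if gen[j] >= gen[i]:
                    raise ValueError("offspring generation not greater than parent's")
            if (s == UNKNOWN) != (d == UNKNOWN):
                raise ValueError("half-known parentage is not supported")
        if not self.founder_mask().any():
            raise ValueError("pedigree has no founders")


def generate_pedigree(
    generation_sizes=DEFAULT_GENERATION_SIZES,
    seed: int = 0,
    mating_rule: str = "avoid_full_sib",
) -> Pedigree:
    """Simulate a closed-line pedigree with the requested generation sizes.

    ``generation_sizes`` is a sequence of ``(n_male, n_female)`` pairs; the
    first generation forms the founder base, every later generation is bred
    from random sire-dam pairs of the previous one. Random pairing avoids
    full-sib and parent-offspring matings whenever an alternative sire
    exists, which slows (but does not prevent) inbreeding accumulation the
    way inbreeding-aware mate allocation does in a real closed nucleus line.
    """
    if len(generation_sizes) == 0:
        raise ValueError("generation_sizes must be non-empty")
    if mating_rule not in ("avoid_full_sib", "random"):
        raise ValueError(f"unknown mating rule {mating_rule!r}")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str, int]] = []
    prev_m: list[int] = []  # row indices of previous-generation males/females
    prev_f: list[int] = []
    parents_of: dict[int, tuple[str, str]] = {}

    for g, (n_m, n_f) in enumerate(generation_sizes, start=1):
        if n_m < 0 or n_f < 0:
            raise ValueError("negative generation size")
        is_last = g == len(generation_sizes)
        if g > 1 and (not prev_m or not prev_f):
            raise ValueError(
                f"generation {g - 1} has no {'males' if not prev_m else 'females'}; "
                "cannot breed the next generation"
            )
        n_off = n_m + n_f
        sexes = np.array(["male"] * n_m + ["female"] * n_f)
        rng.shuffle(sexes)
        new_m: list[int] = []
        new_f: list[int] = []
        if g == 1:
            for k, sex in enumerate(sexes):
                idx = len(rows)
                rows.append((f"G1_{k + 1:04d}", UNKNOWN, UNKNOWN, sex, 1))
                (new_m if sex == "male" else new_f).append(idx)
        else:
            # one sire per dam, avoiding full-sib pairs when alternatives exist
            pair_sire: dict[int, int] = {}
            for dam in prev_f:
                cands = prev_m
                if mating_rule == "avoid_full_sib":
                    ok = [
                        s
                        for s in prev_m
                        if parents_of.get(s) is None
                        or parents_of.get(s) != parents_of.get(dam)
                    ]
                    if ok:
                        cands = ok
                pair_sire[dam] = cands[rng.integers(len(cands))]
            dams = np.asarray(prev_f)
            dam_of = dams[rng.integers(len(dams), size=n_off)]
            for k, sex in enumerate(sexes):
                dam = int(dam_of[k])
                sire = pair_sire[dam]
                idx = len(rows)
                rows.append(
                    (f"G{g}_{k + 1:04d}", rows[sire][0], rows[dam][0], sex, g)
                )
                parents_of[idx] = (rows[sire][0], rows[dam][0])
                (new_m if sex == "male" else new_f).append(idx)
        if not is_last and (n_m == 0 or n_f == 0):
            raise ValueError(f"generation {g} needs both sexes to breed generation {g + 1}")
        prev_m, prev_f = new_m, new_f

    ped = Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# Marker map and haplotype pool
# ---------------------------------------------------------------------------


def make_marker_map(
    n_chrom: int = 2,
    chrom_length_bp: int = 100_000_000,
    snps_per_chrom: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random marker map: uniform positions, ~1 SNP / 50 kb at the defaults."""
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chrom + 1):
        pos = np.sort(
            rng.choice(np.arange(1, chrom_length_bp + 1), size=snps_per_chrom, replace=False)
        )
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{c}_{i + 1}" for i in range(snps_per_chrom)],
                    "chrom": c,
                    "pos_bp": pos.astype(np.int64),
                    "ref": "A",
                    "alt": "B",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class HaplotypePool:
    """Small pool of ancestral haplotypes from which founders are mosaics."""

    alleles: np.ndarray  # (n_anc, m) in {0, 1}
    weights: np.ndarray  # (n_anc,) mosaic segment weights, sums to 1
    switch_rate: float  # expected mosaic switches per Morgan

    @property
    def n_anc(self) -> int:
        return self.alleles.shape[0]

    def __post_init__(self) -> None:
        if self.alleles.size == 0:
            raise ValueError("empty haplotype pool")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()

    def allele_freq(self) -> np.ndarray:
        """Weighted pool allele-1 frequency per SNP."""
        return self.weights @ self.alleles


# defaults frozen from the LD-calibration pilot sweep (see docs/methods.md)
DEFAULT_N_ANC = 5
DEFAULT_WEIGHT_DECAY = 0.65
DEFAULT_SWITCH_RATE = 15.0


def make_pool(
    marker_map: pd.DataFrame,
    n_anc: int = DEFAULT_N_ANC,
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    switch_rate: float = DEFAULT_SWITCH_RATE,
    seed: int = 0,
    freq_beta: tuple[float, float] = (0.6, 0.6),
) -> HaplotypePool:
    """Draw a pool of ancestral haplotypes.

    Per-SNP target frequencies come from a Beta distribution; pool alleles
    are Bernoulli draws, so pool columns are independent across loci and all
    founder LD arises from the shared mosaic indices. Geometric weights
    ``weight_decay**i`` make some pool haplotypes rare, producing a spectrum
    that includes low-MAF SNPs.
    """
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    p = rng.beta(*freq_beta, size=m).clip(0.02, 0.98)
    alleles = (rng.random((n_anc, m)) < p).astype(np.int8)
    weights = weight_decay ** np.arange(n_anc)
    return HaplotypePool(alleles=alleles, weights=weights, switch_rate=switch_rate)


def generate_founder_haplotypes(
    pool: HaplotypePool,
    n_founders: int,
    marker_map: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Mosaic founder haplotypes, shape ``(2 * n_founders, m)`` in {0, 1}.

    Switch points are a Poisson process of rate ``pool.switch_rate`` per
    Morgan along each chromosome; at each switch a new pool haplotype is
    drawn from the pool weights.
    """
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    out = np.empty((2 * n_founders, m), dtype=np.int8)
    chrom = marker_map["chrom"].to_numpy()
    pos_m = morgans(marker_map["pos_bp"].to_numpy())
    for c in np.unique(chrom):
        sel = np.where(chrom == c)[0]
        gpos = pos_m[sel]
        length = gpos[-1] - gpos[0]
        for h in range(2 * n_founders):
            n_sw = rng.poisson(pool.switch_rate * length)
            cuts = np.sort(rng.uniform(gpos[0], gpos[-1], size=n_sw))
            seg = np.searchsorted(cuts, gpos, side="right")  # segment index per SNP
            src = rng.choice(pool.n_anc, size=n_sw + 1, p=pool.weights)
            out[h, sel] = pool.alleles[src[seg], sel]
    return out


# ---------------------------------------------------------------------------
# Genotype panel and gene dropping
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Animals x SNPs dosage table (count of the alt allele; -1 = missing)."""

    animal_ids: list[str]
    marker_map: pd.DataFrame
    dosage: np.ndarray  # (n, m) int8

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.animal_ids) or m != len(self.marker_map):
            raise ValueError("panel dimensions inconsistent")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            list(self.animal_ids), self.marker_map.copy(), self.dosage.copy()
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls."""
        obs = self.dosage != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.dosage, 0).sum(0) / (2.0 * obs.sum(0))

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypePanel":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            [self.animal_ids[i] for i in a],
            self.marker_map.iloc[s].reset_index(drop=True),
            self.dosage[np.ix_(a, s)].copy(),
        )


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_slices: list[np.ndarray],
    chrom_gpos: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete under the Haldane (no-interference) model."""
    gam = np.empty_like(hap_a)
    for sel, gpos in zip(chrom_slices, chrom_gpos):
        length = gpos[-1] - gpos[0]
        n_co = rng.poisson(length)  # crossovers per Morgan
        cuts = np.sort(rng.uniform(gpos[0], gpos[-1], size=n_co))
        parity = (np.searchsorted(cuts, gpos, side="right") + rng.integers(2)) % 2
        gam[sel] = np.where(parity == 0, hap_a[sel], hap_b[sel])
    return gam


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    marker_map: pd.DataFrame,
    seed: int = 0,
    return_phased: bool = False,
):
    """Drop founder haplotypes through the pedigree with Haldane recombination.

    Founders take consecutive haplotype pairs from ``founder_haplotypes``
    (which must hold at least ``2 * n_founders`` rows); every non-founder
    receives one recombinant gamete from each parent. Returns a
    :class:`GenotypePanel` (and the phased ``(2n, m)`` haplotype array when
    ``return_phased``).
    """
    rng = np.random.default_rng(seed)
    sire, dam = pedigree.parent_indices()
    if np.any((sire == -1) != (dam == -1)):
        raise ValueError("animals with exactly one known parent are not supported")
    n = pedigree.n
    m = len(marker_map)
    n_founders = int((sire == -1).sum())
    if founder_haplotypes.shape[0] < 2 * n_founders:
        raise ValueError("not enough founder haplotypes for the pedigree founders")
    chrom = marker_map["chrom"].to_numpy()
    pos_m = morgans(marker_map["pos_bp"].to_numpy())
    chrom_slices = [np.where(chrom == c)[0] for c in np.unique(chrom)]
    chrom_gpos = [pos_m[s] for s in chrom_slices]

    haps = np.empty((2 * n, m), dtype=np.int8)
    next_founder = 0
    for i in range(n):
        if sire[i] == -1:
            haps[2 * i] = founder_haplotypes[2 * next_founder]
            haps[2 * i + 1] = founder_haplotypes[2 * next_founder + 1]
            next_founder += 1
        else:
            s, d = sire[i], dam[i]
            haps[2 * i] = _meiosis(
                haps[2 * s], haps[2 * s + 1], chrom_slices, chrom_gpos, rng
            )
            haps[2 * i + 1] = _meiosis(
                haps[2 * d], haps[2 * d + 1], chrom_slices, chrom_gpos, rng
            )
    dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
    panel = GenotypePanel(pedigree.ids, marker_map.reset_index(drop=True), dosage)
    if return_phased:
        return panel, haps
    return panel


def mask_missing(panel: GenotypePanel, rate: float, seed: int = 0) -> GenotypePanel:
    """Set entries to missing independently at ``rate``; input left unchanged."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    out = panel.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.dosage.shape) < rate
        out.dosage[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# One-call population builder and LD calibration helper
# ---------------------------------------------------------------------------


def simulate_population(
    seed: int = 0,
    generation_sizes=DEFAULT_GENERATION_SIZES,
    n_chrom: int = 2,
    chrom_length_bp: int = 100_000_000,
    snps_per_chrom: int = 2000,
    n_anc: int = DEFAULT_N_ANC,
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    switch_rate: float = DEFAULT_SWITCH_RATE,
    missing_rate: float = 0.01,
):
    """Pedigree + calibrated genotype panel in one call (seeded end to end)."""
    ped = generate_pedigree(generation_sizes, seed=seed)
    mmap = make_marker_map(n_chrom, chrom_length_bp, snps_per_chrom, seed=seed + 1)
    pool = make_pool(
        mmap, n_anc=n_anc, weight_decay=weight_decay, switch_rate=switch_rate,
        seed=seed + 2,
    )
    n_founders = int(ped.founder_mask().sum())
    fh = generate_founder_haplotypes(pool, n_founders, mmap, seed=seed + 3)
    panel = gene_drop(ped, fh, mmap, seed=seed + 4)
    panel = mask_missing(panel, missing_rate, seed=seed + 5)
    return ped, panel


def calibrate_pool(
    n_anc_grid=(4, 5, 6, 8),
    switch_grid=(5.0, 10.0, 15.0, 25.0),
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    target_r2: float = 0.20,
    seed: int = 0,
    snps_per_chrom: int = 800,
) -> pd.DataFrame:
    """Pilot sweep: mean r^2 near 1.0 Mb for each (n_anc, switch_rate).

    Used once to choose the frozen defaults; returns the sweep table sorted
    by distance to ``target_r2``.
    """
    from .qc import ld_decay_curve, mean_r2_near

    rows = []
    for n_anc in n_anc_grid:
        for sw in switch_grid:
            _, panel = simulate_population(
                seed=seed,
                snps_per_chrom=snps_per_chrom,
                n_anc=n_anc,
                weight_decay=weight_decay,
                switch_rate=sw,
                missing_rate=0.0,
            )
            curve = ld_decay_curve(panel)
            r2 = mean_r2_near(curve, 1_000_000)
            rows.append({"n_anc": n_anc, "switch_rate": sw, "r2_at_1mb": r2})
    df = pd.DataFrame(rows)
    df["gap"] = (df["r2_at_1mb"] - target_r2).abs()
    return df.sort_values("gap").reset_index(drop=True)
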