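"""Outgroup f3 shared-drift statistics with block-jackknife errors.

f3(A, B; O) is the average over usable SNPs of (p_O - p_A)(p_O - p_B),
where p are sample alternate-allele frequencies; for an outgroup O it
measures the shared drift of A and B since their divergence from O.
Genotypes come from EIGENSTRAT-style geno/snp/ind text triplets; a
pseudo-haploid individual (calls in {0, 2}) contributes a single allele
draw per site, with no heterozygosity correction (outgroup mode).
Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (block weights = usable-site counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = 9


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes: sites x individuals alternate-allele counts.

    ``calls[s, i]`` is 0/1/2 copies of the alternate allele (the second
    allele column of the snp table) or -1 for missing.  Pseudo-haploid
    individuals carry calls in {0, 2} representing one drawn allele.
    """

    snp: pd.DataFrame  # columns: snp_id, chrom, gen_pos, pos, ref, alt
    calls: np.ndarray  # n_sites x n_ind, int8; -1 = missing
    ind: pd.DataFrame  # columns: id, sex, population
    pseudo_haploid: np.ndarray | None = None  # bool per individual

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.snp), len(self.ind)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.snp)} sites, {len(self.ind)} individuals)"
            )
        for chrom, grp in self.snp.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        if self.pseudo_haploid is None:
            # infer: an individual with no het call anywhere is treated as
            # diploid unless flagged; default to all-diploid
            self.pseudo_haploid = np.zeros(len(self.ind), dtype=bool)

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.ind["population"]:
            seen.setdefault(p, None)
        return tuple(seen)

    def individuals_of(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.ind["population"] == population).to_numpy())
        if len(idx) == 0:
            raise GenotypeError(f"no individuals in population {population!r}")
        return idx

    def allele_frequencies(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(alt-allele frequency, called-allele count) per site.

        Diploid calls contribute two allele observations, pseudo-haploid
        calls one; sites with no called individual get frequency NaN.
        """
        idx = self.individuals_of(population)
        sub = self.calls[:, idx].astype(float)
        ph = self.pseudo_haploid[idx]
        called = sub >= 0
        alt = np.where(called, sub, 0.0)
        ploidy = np.where(ph, 1.0, 2.0)
        alt_counts = np.where(ph[None, :], alt / 2.0, alt)
        denom = (called * ploidy[None, :]).sum(axis=1)
        num = (alt_counts * called).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freq = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
        return freq, denom


def read_genotypes(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read an EIGENSTRAT-style triplet (text geno / snp / ind)."""
    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "population"],
        dtype=str,
    )
    snp = pd.read_csv(
        snp_path, sep=r"\s+", header=None,
        names=["snp_id", "chrom", "gen_pos", "pos", "ref", "alt"],
        dtype={"snp_id": str, "chrom": str, "ref": str, "alt": str},
    )
    snp["pos"] = snp["pos"].astype(int)
    lines = Path(geno_path).read_text().split()
    if len(lines) != len(snp):
        raise GenotypeError(
            f"{geno_path}: {len(lines)} genotype rows for {len(snp)} snps"
        )
    calls = np.empty((len(snp), len(ind)), dtype=np.int8)
    for s, line in enumerate(lines):
        if len(line) != len(ind):
            raise GenotypeError(
                f"{geno_path} line {s + 1}: {len(line)} codes for "
                f"{len(ind)} individuals"
            )
        row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
        bad = ~np.isin(row, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError(
                f"{geno_path} line {s + 1}: invalid genotype code "
                f"{line[int(np.flatnonzero(bad)[0])]!r}"
            )
        calls[s] = np.where(row == MISSING, -1, row)
    return GenotypeMatrix(snp=snp, calls=calls, ind=ind)


def write_genotypes(G: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    """Write the triplet back out (round-trip inverse of read_genotypes)."""
    codes = np.where(G.calls < 0, MISSING, G.calls).astype(np.uint8) + ord("0")
    with open(geno_path, "w") as fh:
        for row in codes:
            fh.write(row.tobytes().decode() + "\n")
    G.snp.to_csv(snp_path, sep="\t", header=False, index=False)
    G.ind.to_csv(ind_path, sep="\t", header=False, index=False)


@dataclass
class F3Result:
    pop_a: str
    pop_b: str
    outgroup: str
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "A": self.pop_a,
                "B": self.pop_b,
                "outgroup": self.outgroup,
                "f3": self.estimate,
                "se": self.se,
                "Z": self.z,
                "n_sites": self.n_sites,
                "n_blocks": self.n_blocks,
            }
        )


def f3_per_site(
    G: GenotypeMatrix, pop_a: str, pop_b: str, outgroup: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site f3 numerators and the usable-site mask.

    A site is usable when each of the three populations has at least one
    called individual there.
    """
    pa, _ = G.allele_frequencies(pop_a)
    pb, _ = G.allele_frequencies(pop_b)
    po, _ = G.allele_frequencies(outgroup)
    usable = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(po))
    with np.errstate(invalid="ignore"):
        vals = (po - pa) * (po - pb)
    return vals, usable


def outgroup_f3(
    G: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    outgroup: str,
    block_size: int = 5_000_000,
) -> F3Result:
    """Outgroup f3 point estimate with block-jackknife standard error."""
    vals, usable = f3_per_site(G, pop_a, pop_b, outgroup)
    n_used = int(usable.sum())
    if n_used == 0:
        raise GenotypeError("no usable sites for f3")
    est, se, n_blocks = block_jackknife(
        vals[usable],
        G.snp.loc[usable, ["chrom", "pos"]],
        block_size=block_size,
    )
    z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    return F3Result(pop_a, pop_b, outgroup, est, se, float(z), n_used, n_blocks)


def block_jackknife(
    per_site_values: np.ndarray,
    site_positions: pd.DataFrame,
    block_size: int = 5_000_000,
) -> tuple[float, float, int]:
    """Weighted delete-one block jackknife over contiguous genomic blocks.

    Blocks are ``block_size``-bp windows within each chromosome; block
    weights are their site counts.  Returns (estimate, SE, n_blocks); the
    estimate is the plain all-site mean.  Raises with fewer than 2
    non-empty blocks.
    """
    v = np.asarray(per_site_values, dtype=float)
    if len(v) != len(site_positions):
        raise GenotypeError("values and positions differ in length")
    chrom = site_positions["chrom"].to_numpy()
    pos = site_positions["pos"].to_numpy()
    block_key = pd.Series(
        [f"{c}:{p // block_size}" for c, p in zip(chrom, pos)]
    )
    codes = block_key.astype("category").cat.codes.to_numpy()
    g = codes.max() + 1 if len(codes) else 0
    sums = np.bincount(codes, weights=v, minlength=g)
    counts = np.bincount(codes, minlength=g)
    nonempty = counts > 0
    sums, counts = sums[nonempty], counts[nonempty]
    g = len(counts)
    if g < 2:
        raise GenotypeError(
            "block jackknife needs >= 2 non-empty blocks; widen the data or "
            "shrink block_size"
        )
    n = counts.sum()
    total = sums.sum()
    theta = total / n
    # delete-one-block estimates and Busing-style weighted jackknife variance
    theta_del = (total - sums) / (n - counts)
    h = n / counts
    tau = h * theta - (h - 1.0) * theta_del
    theta_j = g * theta - np.sum((1.0 - counts / n) * theta_del)
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return float(theta), float(np.sqrt(var)), int(g)
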