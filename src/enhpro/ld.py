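"""Pairwise linkage disequilibrium from a genotype panel.

r-squared is the standard D^2 / (pA*pa*pB*pb) with D = pAB - pA*pB.  For
phased panels the two-locus haplotype frequencies are exact counts; for
unphased panels they are maximum-likelihood estimates from an EM that
resolves the double-heterozygote phase ambiguity.  Missing genotypes are
handled by pairwise-complete deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Variant

logger = logging.getLogger(__name__)


class LdError(Exception):
    """Base class for LD-computation failures."""


class MonomorphicLocusError(LdError):
    """LD is undefined when either locus is monomorphic."""


class InsufficientDataError(LdError):
    """Fewer than two samples with complete calls at both loci."""


@dataclass(frozen=True)
class SiteRecord:
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypePanel:
    """Diploid genotype matrix over a set of biallelic SNV sites.

    ``dosage`` is samples x loci alt-allele dosage in {0,1,2}, -1 = missing.
    If ``phased``, ``haplotypes`` is (2*samples) x loci with alleles in
    {0,1}, -1 = missing; haplotypes 2i and 2i+1 belong to sample i.
    """

    samples: list[str]
    loci: list[SiteRecord]
    dosage: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None
    _rsid_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage dimensions must be samples x loci")
        valid = np.isin(self.dosage, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        if self.phased and self.haplotypes is None:
            raise ValueError("phased panel requires haplotypes")
        self._rsid_index = {site.rsid: i for i, site in enumerate(self.loci)}

    def locus_index(self, rsid: str) -> int | None:
        return self._rsid_index.get(rsid)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes.

    A/a are the ref/alt alleles at the first locus, B/b at the second.
    """

    pAB: float
    pAb: float
    paB: float
    pab: float

    def __post_init__(self) -> None:
        total = self.pAB + self.pAb + self.paB + self.pab
        if min(self.pAB, self.pAb, self.paB, self.pab) < -1e-12:
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1, got {total}")

    @property
    def d(self) -> float:
        pA = self.pAB + self.pAb
        pB = self.pAB + self.paB
        return self.pAB - pA * pB


# ---------------------------------------------------------------------------
# EM estimator

def _genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint alt-dosage genotype counts."""
    counts = np.zeros((3, 3), dtype=float)
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((g1 == a) & (g2 == b))
    return counts


def _log_likelihood(p: np.ndarray, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of genotype counts under haplotype freqs.

    ``p`` holds (p_refref, p_refalt, p_altref, p_altalt) = (pAB, pAb, paB, pab)
    with a/b denoting the alt alleles.
    """
    pAB, pAb, paB, pab = p
    # genotype (g1, g2) = alt dosages; probability from random union of gametes
    probs = np.empty((3, 3))
    probs[0, 0] = pAB * pAB
    probs[0, 1] = 2 * pAB * pAb
    probs[0, 2] = pAb * pAb
    probs[1, 0] = 2 * pAB * paB
    probs[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    probs[1, 2] = 2 * pAb * pab
    probs[2, 0] = paB * paB
    probs[2, 1] = 2 * paB * pab
    probs[2, 2] = pab * pab
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return -np.inf
    return float(np.sum(counts[mask] * logp[mask]))


def _em_iterate(
    p0: np.ndarray, counts: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, list[float]]:
    """Run EM from an initial frequency vector; returns (freqs, loglik trace)."""
    n_chrom = 2.0 * counts.sum()
    # fixed haplotype contributions from unambiguous genotypes
    base = np.zeros(4)  # (AB, Ab, aB, ab) with a/b = alt
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_dh = counts[1, 1]
    p = p0.copy()
    trace = [_log_likelihood(p, counts)]
    for _ in range(max_iter):
        pAB, pAb, paB, pab = p
        denom = pAB * pab + pAb * paB
        w = 0.5 if denom == 0 else (pAB * pab) / denom
        c = base.copy()
        c[0] += n_dh * w
        c[3] += n_dh * w
        c[1] += n_dh * (1 - w)
        c[2] += n_dh * (1 - w)
        p_new = c / n_chrom
        trace.append(_log_likelihood(p_new, counts))
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    return p, trace


def haplotype_freqs_em(
    panel: GenotypePanel,
    locus1: int | str,
    locus2: int | str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Two-locus haplotype frequencies from the panel.

    Phased panels give exact haplotype counts over 2n chromosomes; unphased
    panels give the EM maximum-likelihood estimate.  The EM is started from
    linkage equilibrium and from both full phase assignments of the double
    heterozygotes; among converged solutions of equal likelihood the one
    with D >= 0 is kept, which makes the estimator deterministic.
    """
    i = panel.locus_index(locus1) if isinstance(locus1, str) else locus1
    j = panel.locus_index(locus2) if isinstance(locus2, str) else locus2
    if i is None or j is None:
        raise KeyError("locus not present in panel")

    g1 = panel.dosage[:, i]
    g2 = panel.dosage[:, j]
    complete = (g1 >= 0) & (g2 >= 0)
    if int(complete.sum()) < 2:
        raise InsufficientDataError(
            f"fewer than 2 samples with complete calls at loci {locus1}, {locus2}"
        )
    g1, g2 = g1[complete], g2[complete]
    if len(set(g1.tolist())) == 1 and g1[0] in (0, 2):
        raise MonomorphicLocusError(f"locus {locus1} is monomorphic")
    if len(set(g2.tolist())) == 1 and g2[0] in (0, 2):
        raise MonomorphicLocusError(f"locus {locus2} is monomorphic")

    if panel.phased:
        assert panel.haplotypes is not None
        keep = np.repeat(complete, 2)
        h1 = panel.haplotypes[keep, i]
        h2 = panel.haplotypes[keep, j]
        n = float(len(h1))
        pAB = float(np.sum((h1 == 0) & (h2 == 0))) / n
        pAb = float(np.sum((h1 == 0) & (h2 == 1))) / n
        paB = float(np.sum((h1 == 1) & (h2 == 0))) / n
        pab = float(np.sum((h1 == 1) & (h2 == 1))) / n
        return HaplotypeFreqs(pAB, pAb, paB, pab)

    counts = _genotype_counts(g1, g2)
    n_chrom = 2.0 * counts.sum()
    p_alt1 = (counts[1, :].sum() + 2 * counts[2, :].sum()) / n_chrom
    p_alt2 = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / n_chrom
    pA, pB = 1 - p_alt1, 1 - p_alt2
    inits = [np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])]
    # full phase assignments of the double heterozygotes (AB/ab vs Ab/aB)
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_dh = counts[1, 1]
    if n_dh > 0:
        for split in ((n_dh, 0.0), (0.0, n_dh)):
            c = base.copy()
            c[0] += split[0]
            c[3] += split[0]
            c[1] += split[1]
            c[2] += split[1]
            inits.append(c / n_chrom)

    best: tuple[float, float, np.ndarray] | None = None
    for p0 in inits:
        p, trace = _em_iterate(p0, counts, tol, max_iter)
        ll = trace[-1]
        freqs = HaplotypeFreqs(*np.clip(p, 0.0, 1.0) / np.clip(p, 0.0, 1.0).sum())
        key = (ll, freqs.d)
        if best is None or ll > best[0] + 1e-10 or (
            abs(ll - best[0]) <= 1e-10 and freqs.d > best[1]
        ):
            best = (ll, freqs.d, p)
    assert best is not None
    p = np.clip(best[2], 0.0, 1.0)
    p = p / p.sum()
    return HaplotypeFreqs(*p)


def r_squared(freqs: HaplotypeFreqs) -> float:
    """Squared allelic correlation; undefined when a marginal is 0 or 1."""
    pA = freqs.pAB + freqs.pAb
    pB = freqs.pAB + freqs.paB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        raise MonomorphicLocusError("marginal allele frequency is 0 or 1")
    d = freqs.pAB - pA * pB
    return float(np.clip(d * d / (pA * pa * pB * pb), 0.0, 1.0))


# ---------------------------------------------------------------------------
# proxy expansion

def _phased_r2_to_column(panel: GenotypePanel, i: int, js: np.ndarray) -> np.ndarray:
    """Vectorized r^2 between locus i and each locus in js (phased, complete)."""
    assert panel.haplotypes is not None
    h = panel.haplotypes
    x = h[:, i].astype(float)
    y = h[:, js].astype(float)
    px = x.mean()
    py = y.mean(axis=0)
    d = (x[:, None] * y).mean(axis=0) - px * py
    denom = px * (1 - px) * py * (1 - py)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return np.clip(r2, 0.0, 1.0)


def expand_proxies(
    index_snps: list[Variant],
    panel: GenotypePanel,
    r2_threshold: float = 0.8,
    search_window_bp: int = 500_000,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> list[Variant]:
    """Expand index SNPs into proxy sets at an r^2 threshold.

    Every panel site within +/- ``search_window_bp`` of an index SNP on the
    same contig with r^2 >= threshold becomes a proxy carrying the index
    rsid and r^2.  A site tagging several index SNPs keeps its strongest
    link; index SNPs themselves are retained unchanged.
    """
    positions: dict[str, np.ndarray] = {}
    order: dict[str, np.ndarray] = {}
    chroms = np.array([s.chrom for s in panel.loci])
    pos_arr = np.array([s.pos for s in panel.loci])
    for chrom in np.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        idx = idx[np.argsort(pos_arr[idx], kind="stable")]
        positions[chrom] = pos_arr[idx]
        order[chrom] = idx

    index_rsids = {v.rsid for v in index_snps}
    best: dict[str, tuple[float, Variant, Variant]] = {}  # rsid -> (r2, site, index)
    fully_phased = (
        panel.phased
        and panel.haplotypes is not None
        and not (panel.haplotypes < 0).any()
    )
    for index in index_snps:
        i = panel.locus_index(index.rsid)
        if i is None:
            logger.warning("index SNP %s absent from panel; skipped", index.rsid)
            continue
        chrom = panel.loci[i].chrom
        pos = panel.loci[i].pos
        lo = np.searchsorted(positions[chrom], pos - search_window_bp, side="left")
        hi = np.searchsorted(positions[chrom], pos + search_window_bp, side="right")
        js = order[chrom][lo:hi]
        js = js[js != i]
        if len(js) == 0:
            continue
        if fully_phased:
            r2s = _phased_r2_to_column(panel, i, js)
        else:
            r2s = np.empty(len(js))
            for k, j in enumerate(js):
                try:
                    r2s[k] = r_squared(
                        haplotype_freqs_em(panel, i, int(j), tol, max_iter)
                    )
                except LdError:
                    r2s[k] = np.nan
        for j, r2 in zip(js, r2s):
            if np.isnan(r2):
                logger.debug("undefined LD for %s; skipped", panel.loci[j].rsid)
                continue
            if r2 < r2_threshold:
                continue
            site = panel.loci[int(j)]
            if site.rsid in index_rsids:
                continue
            prev = best.get(site.rsid)
            if prev is None or r2 > prev[0]:
                proxy = Variant(
                    rsid=site.rsid,
                    chrom=site.chrom,
                    pos=site.pos,
                    ref_allele=site.ref,
                    alt_allele=site.alt,
                    source="proxy",
                    pvalue=None,
                    index_rsid=index.rsid,
                    r2_to_index=float(r2),
                    reported_genes=list(index.reported_genes),
                )
                best[site.rsid] = (float(r2), proxy, index)

    proxies = sorted(
        (entry[1] for entry in best.values()), key=lambda v: (v.chrom, v.pos, v.rsid)
    )
    return list(index_snps) + proxies


def write_proxy_table(variants: list[Variant], path) -> None:
    """Emit the proxy TSV (index_rsid, proxy_rsid, chrom, pos, r2)."""
    with open(path, "w") as fh:
        fh.write("index_rsid\tproxy_rsid\tchrom\tpos\tr2\n")
        for v in variants:
            if v.source == "proxy":
                fh.write(
                    f"{v.index_rsid}\t{v.rsid}\t{v.chrom}\t{v.pos}\t{v.r2_to_index:.6g}\n"
                )
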