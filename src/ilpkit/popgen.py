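"""Population genetics on codominant ILP genotypes.

Covers the full downstream analysis of a scored marker panel: band-to-
genotype conversion, allele frequencies, per-locus diversity indices
(Na, Ne, Shannon I, observed/expected homo- and heterozygosity, Nei gene
diversity H, PIC), per-population summaries with PPB, Wright/Nei
F-statistics with gene flow, AMOVA on band-presence vectors, Nei genetic
identity and distance between populations, neighbour-joining and UPGMA
trees, and principal coordinates analysis.

Conventions follow the classic Popgene/PowerMarker/GenAlEx lineage of
tools: Shannon index in natural log; expected heterozygosity with
Levene's small-sample correction 2N/(2N-1) (plain Nei H is reported
alongside); F-statistics as sample-size-weighted Nei (1977) G_st with
ratio-of-averages combining over loci; AMOVA on squared Euclidean
distances of 0/1 band vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import skbio

Genotype = tuple | None  # unordered allele pair, or None for missing


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class BandMatrix:
    """Binary presence/absence electrophoresis bands.

    ``df``: individuals x band columns (MultiIndex (locus, band_size)),
    entries in {0,1}. ``populations``: population label per individual.
    """

    def __init__(self, df: pd.DataFrame, populations: pd.Series):
        vals = df.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("band matrix entries must be 0/1")
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
            raise ValueError("band columns must be a (locus, band_size) MultiIndex")
        self.df = df.astype(int)
        self.populations = populations.reindex(df.index)

    @property
    def loci(self) -> list:
        seen: list = []
        for locus in self.df.columns.get_level_values(0):
            if locus not in seen:
                seen.append(locus)
        return seen

    def to_csv(self, path: str) -> None:
        out = self.df.copy()
        out.insert(0, ("population", ""), self.populations)
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "BandMatrix":
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        pop_col = df.columns[0]
        populations = df[pop_col]
        df = df.drop(columns=[pop_col])
        df.columns = pd.MultiIndex.from_tuples(
            [(locus, int(float(size))) for locus, size in df.columns]
        )
        return cls(df, populations)


class GenotypeTable:
    """Individuals x loci codominant genotype calls.

    ``df`` holds, per cell, a sorted allele tuple (a, b) or None when the
    call is missing. Allele labels are band sizes.
    """

    def __init__(self, df: pd.DataFrame, populations: pd.Series):
        self.df = df
        self.populations = populations.reindex(df.index)

    @property
    def loci(self) -> list:
        return list(self.df.columns)

    @property
    def individuals(self) -> list:
        return list(self.df.index)

    def subset(self, individuals) -> "GenotypeTable":
        return GenotypeTable(self.df.loc[individuals], self.populations.loc[individuals])

    def population(self, label) -> "GenotypeTable":
        mask = self.populations == label
        if not mask.any():
            raise ValueError(f"empty population {label!r}")
        return self.subset(self.df.index[mask])

    def to_genalex_csv(self, path: str) -> None:
        """Two columns per locus, alleles as band sizes, 0 = missing."""
        rows = []
        for ind in self.df.index:
            row = {"individual": ind, "population": self.populations[ind]}
            for locus in self.df.columns:
                g = self.df.at[ind, locus]
                a, b = (0, 0) if g is None else g
                row[f"{locus}.1"] = a
                row[f"{locus}.2"] = b
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_genalex_csv(cls, path: str) -> "GenotypeTable":
        raw = pd.read_csv(path)
        cols = list(raw.columns)
        loci = sorted({c[:-2] for c in cols if c.endswith(".1")},
                      key=lambda l: cols.index(f"{l}.1"))
        data = {}
        for locus in loci:
            col = []
            for a, b in zip(raw[f"{locus}.1"], raw[f"{locus}.2"]):
                col.append(None if a == 0 or b == 0 else tuple(sorted((a, b))))
            data[locus] = col
        df = pd.DataFrame(data, index=raw["individual"])
        pops = pd.Series(raw["population"].to_numpy(), index=raw["individual"])
        return cls(df, pops)


# ---------------------------------------------------------------------------
# Band scoring
# ---------------------------------------------------------------------------

def bands_to_genotypes(bands: BandMatrix) -> GenotypeTable:
    """Codominant scoring: one band -> homozygote, two bands ->
    heterozygote, zero or more than two bands -> missing call."""
    data: dict = {}
    for locus in bands.loci:
        sub = bands.df[locus]
        sizes = list(sub.columns)
        col = []
        for ind in bands.df.index:
            present = [s for s in sizes if sub.at[ind, s] == 1]
            if len(present) == 1:
                col.append((present[0], present[0]))
            elif len(present) == 2:
                col.append(tuple(sorted(present)))
            else:
                col.append(None)
        data[locus] = col
    df = pd.DataFrame(data, index=bands.df.index)
    return GenotypeTable(df, bands.populations)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    genos: GenotypeTable, per_population: bool = False
):
    """Allele frequency tables (allele count / 2 x typed individuals).

    Pooled: {locus: Series(allele -> freq)}. With ``per_population``:
    {population: {locus: Series}}. Loci with zero typed individuals in a
    stratum are omitted from that stratum's table.
    """
    if per_population:
        return {
            pop: allele_frequencies(genos.population(pop))
            for pop in pd.unique(genos.populations)
        }
    freqs: dict = {}
    for locus in genos.loci:
        counts: dict = {}
        for g in genos.df[locus]:
            if g is None:
                continue
            for allele in g:
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        ser = pd.Series(counts, dtype=float).sort_index() / total
        freqs[locus] = ser
    return freqs


def typed_count(genos: GenotypeTable, locus) -> int:
    return int(sum(1 for g in genos.df[locus] if g is not None))


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusDiversity:
    locus: object
    na: int
    ne: float
    shannon_i: float
    obs_ho: float
    obs_he: float
    exp_ho: float
    exp_he: float
    h: float
    pic: float  # fraction in [0, 1]


def pic_from_frequencies(p: np.ndarray) -> float:
    """Polymorphic information content 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    s2 = float(np.sum(p ** 2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - s2 - cross


def locus_diversity(
    genos: GenotypeTable, locus, levene: bool = True
) -> LocusDiversity:
    """Diversity indices at one locus from pooled allele frequencies.

    H is plain Nei gene diversity 1 - sum p^2; Exp_He additionally carries
    Levene's 2N/(2N-1) correction when ``levene`` (the default), which is
    why the two can differ in the last digit.
    """
    freqs = allele_frequencies(genos)
    if locus not in freqs:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    p = freqs[locus].to_numpy()
    n_typed = typed_count(genos, locus)
    s2 = float(np.sum(p ** 2))
    h = 1.0 - s2
    ne = 1.0 / s2
    shannon = float(-np.sum(p * np.log(p)))
    if levene and n_typed > 0:
        exp_he = (2 * n_typed / (2 * n_typed - 1)) * h if 2 * n_typed > 1 else h
    else:
        exp_he = h
    homo = sum(1 for g in genos.df[locus] if g is not None and g[0] == g[1])
    obs_ho = homo / n_typed if n_typed else float("nan")
    return LocusDiversity(
        locus=locus, na=int(np.sum(p > 0)), ne=ne, shannon_i=shannon,
        obs_ho=obs_ho, obs_he=1.0 - obs_ho, exp_ho=1.0 - exp_he,
        exp_he=exp_he, h=h, pic=pic_from_frequencies(np.asarray(p)),
    )


def diversity_table(genos: GenotypeTable, levene: bool = True) -> pd.DataFrame:
    """Per-locus diversity indices (PIC as a percentage), plus a Mean row."""
    rows = []
    for locus in genos.loci:
        d = locus_diversity(genos, locus, levene=levene)
        rows.append({
            "locus": d.locus, "Na": float(d.na), "Ne": d.ne, "I": d.shannon_i,
            "Obs_Ho": d.obs_ho, "Obs_He": d.obs_he, "Exp_Ho": d.exp_ho,
            "Exp_He": d.exp_he, "H": d.h, "PIC_pct": 100.0 * d.pic,
        })
    df = pd.DataFrame(rows).set_index("locus")
    df.loc["Mean"] = df.mean()
    return df


def population_diversity(genos: GenotypeTable) -> pd.DataFrame:
    """Per-population means of Na, Ne, I, H over loci plus PPB% (share of
    loci with at least two observed alleles)."""
    rows = []
    for pop in pd.unique(genos.populations):
        sub = genos.population(pop)
        divs = [locus_diversity(sub, locus) for locus in sub.loci
                if typed_count(sub, locus) > 0]
        if not divs:
            raise ValueError(f"population {pop!r} has no typed loci")
        rows.append({
            "population": pop,
            "n": len(sub.individuals),
            "Na": float(np.mean([d.na for d in divs])),
            "Ne": float(np.mean([d.ne for d in divs])),
            "I": float(np.mean([d.shannon_i for d in divs])),
            "H": float(np.mean([d.h for d in divs])),
            "PPB_pct": 100.0 * np.mean([d.na >= 2 for d in divs]),
        })
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FStats:
    fis: float
    fit: float
    fst: float
    nm: float | None


def f_statistics(genos: GenotypeTable) -> FStats:
    """Nei (1977)-style fixation indices over all loci and populations.

    Per locus: Ho = sample-size-weighted observed heterozygosity, Hs =
    weighted mean within-population expected heterozygosity (1 - sum p^2),
    Ht = expected heterozygosity of the weighted pooled frequencies.
    Multi-locus indices combine by ratio of locus averages; gene flow
    Nm = 0.25 (1 - Fst)/Fst.
    """
    pops = list(pd.unique(genos.populations))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    subs = {p: genos.population(p) for p in pops}
    ho_l, hs_l, ht_l = [], [], []
    for locus in genos.loci:
        ns, hos, hss, pbars = [], [], [], []
        for p in pops:
            sub = subs[p]
            n_k = typed_count(sub, locus)
            if n_k == 0:
                continue
            f = allele_frequencies(sub)[locus]
            het = sum(1 for g in sub.df[locus] if g is not None and g[0] != g[1])
            ns.append(n_k)
            hos.append(het / n_k)
            hss.append(1.0 - float(np.sum(f.to_numpy() ** 2)))
            pbars.append(f)
        if not ns:
            continue
        w = np.array(ns, dtype=float)
        w /= w.sum()
        ho_l.append(float(np.dot(w, hos)))
        hs_l.append(float(np.dot(w, hss)))
        pooled = pd.concat(
            [f * wk for f, wk in zip(pbars, w)], axis=1
        ).fillna(0.0).sum(axis=1)
        ht_l.append(1.0 - float(np.sum(pooled.to_numpy() ** 2)))
    ho_bar, hs_bar, ht_bar = map(np.mean, (ho_l, hs_l, ht_l))
    if ht_bar == 0:
        return FStats(float("nan"), float("nan"), float("nan"), None)
    fis = 1.0 - ho_bar / hs_bar if hs_bar > 0 else float("nan")
    fit = 1.0 - ho_bar / ht_bar
    fst = (ht_bar - hs_bar) / ht_bar
    nm = 0.25 * (1.0 - fst) / fst if fst > 0 else None
    return FStats(float(fis), float(fit), float(fst), nm)


def fst_finite_demes_correction(gst: float, n_demes: int) -> float:
    """Invert the finite-deme bias of G_st-style Fst.

    Differentiation measured among K sampled demes relates to the
    island-model/Balding-Nichols parameter F as
    G = F (K-1)/K / (1 - F/K); this returns F = G K / (K - 1 + G).
    Use when comparing an estimate against a simulation's target Fst.
    """
    if n_demes < 2:
        raise ValueError("need at least two demes")
    return gst * n_demes / (n_demes - 1 + gst)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pmv_among: float  # percent
    pmv_within: float
    n0: float
    p_value: float | None = None


def variance_components_to_pmv(components: list[float]) -> list[float]:
    """Percentages of molecular variance; negative components truncate
    to zero before normalisation."""
    trunc = [max(c, 0.0) for c in components]
    total = sum(trunc)
    if total == 0:
        return [0.0 for _ in trunc]
    return [100.0 * c / total for c in trunc]


def _amova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def amova(
    data: BandMatrix | pd.DataFrame,
    populations: pd.Series | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA (among vs within populations) on squared Euclidean
    distances of 0/1 band-presence vectors.

    ``data`` may be a BandMatrix (populations taken from it) or a plain
    0/1 DataFrame with an aligned populations Series. The optional
    permutation test shuffles population labels and compares the observed
    among-population variance component.
    """
    if isinstance(data, BandMatrix):
        mat = data.df.to_numpy(dtype=float)
        pops = data.populations.to_numpy()
    else:
        mat = data.to_numpy(dtype=float)
        if populations is None:
            raise ValueError("populations required with a plain DataFrame")
        pops = populations.reindex(data.index).to_numpy()
    n = mat.shape[0]
    labels, counts = np.unique(pops, return_counts=True)
    n_pops = len(labels)
    if n_pops < 2:
        raise ValueError("need at least two populations")
    if (counts < 2).any():
        raise ValueError("every population needs at least two individuals")
    # pairwise squared Euclidean distances
    gram = mat @ mat.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    np.fill_diagonal(d2, 0.0)

    ss_total, ss_within = _amova_ss(d2, pops)
    ss_among = ss_total - ss_within
    df_among, df_within = n_pops - 1, n - n_pops
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (counts ** 2).sum() / n) / (n_pops - 1)
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    pmv = variance_components_to_pmv([sigma2_among, sigma2_within])

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pops)
            sst_p, ssw_p = _amova_ss(d2, perm)
            ssa_p = sst_p - ssw_p
            sa_p = (ssa_p / df_among - ssw_p / df_within) / n0
            if sa_p >= sigma2_among:
                exceed += 1
        p_value = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(
        df_among=df_among, df_within=df_within,
        ss_among=float(ss_among), ss_within=float(ss_within),
        ss_total=float(ss_total),
        sigma2_among=float(sigma2_among), sigma2_within=float(sigma2_within),
        pmv_among=pmv[0], pmv_within=pmv[1], n0=float(n0), p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Nei identity / distance
# ---------------------------------------------------------------------------

def nei_identity_distance(freqs_a: dict, freqs_b: dict) -> tuple[float, float]:
    """Nei (1972) genetic identity S and standard distance D = -ln S over
    the shared locus set."""
    shared = [l for l in freqs_a if l in freqs_b]
    if not shared:
        raise ValueError("no shared loci")
    jx, jy, jxy = [], [], []
    for locus in shared:
        pa, pb = freqs_a[locus].align(freqs_b[locus], fill_value=0.0)
        jx.append(float(np.sum(pa.to_numpy() ** 2)))
        jy.append(float(np.sum(pb.to_numpy() ** 2)))
        jxy.append(float(np.sum(pa.to_numpy() * pb.to_numpy())))
    s = float(np.mean(jxy) / math.sqrt(np.mean(jx) * np.mean(jy)))
    d = float("inf") if s <= 0 else -math.log(s)
    return s, d


def pairwise_nei(genos: GenotypeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population x population Nei identity and distance matrices."""
    per_pop = allele_frequencies(genos, per_population=True)
    pops = list(per_pop)
    S = pd.DataFrame(np.eye(len(pops)), index=pops, columns=pops)
    D = pd.DataFrame(np.zeros((len(pops), len(pops))), index=pops, columns=pops)
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            b = pops[j]
            s, d = nei_identity_distance(per_pop[a], per_pop[b])
            S.iloc[i, j] = S.iloc[j, i] = s
            D.iloc[i, j] = D.iloc[j, i] = d
    return S, D


# ---------------------------------------------------------------------------
# Band distances (dominant scoring, e.g. across species)
# ---------------------------------------------------------------------------

def band_distance_matrix(
    presence: pd.DataFrame, metric: str = "simple_matching"
) -> pd.DataFrame:
    """Pairwise distances between rows of a 0/1 band table.

    simple_matching: 1 - (matches / columns); jaccard: 1 - |A&B|/|A|B|.
    """
    x = presence.to_numpy(dtype=float)
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i], x[j]
            if metric == "simple_matching":
                sim = np.mean(a == b)
            elif metric == "jaccard":
                union = np.sum((a + b) > 0)
                sim = np.sum((a * b) > 0) / union if union else 1.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = 1.0 - sim
    return pd.DataFrame(out, index=presence.index, columns=presence.index)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _check_distance(dm: pd.DataFrame) -> None:
    a = dm.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("distance matrix diagonal must be zero")


def nj_tree(dm: pd.DataFrame) -> skbio.TreeNode:
    """Unrooted Saitou-Nei neighbour-joining tree with branch lengths."""
    _check_distance(dm)
    if dm.shape[0] < 3:
        raise ValueError("need at least three taxa")
    sk_dm = skbio.DistanceMatrix(dm.to_numpy(dtype=float), ids=[str(i) for i in dm.index])
    return skbio.tree.nj(sk_dm)


def upgma_tree(
    matrix: pd.DataFrame,
    cut_threshold: float | None = None,
    is_similarity: bool = False,
) -> tuple[str, pd.Series | None]:
    """Average-linkage (UPGMA) dendrogram as a Newick string, with an
    optional cluster assignment from cutting the dendrogram.

    When ``is_similarity`` the matrix holds similarities S and is
    converted to distance 1 - S; a similarity ``cut_threshold`` s is then
    applied as a distance cut at 1 - s.
    """
    labels = [str(i) for i in matrix.index]
    dmat = (1.0 - matrix) if is_similarity else matrix.copy()
    if is_similarity:
        np.fill_diagonal(dmat.values, 0.0)
    _check_distance(dmat)
    z = hierarchy.linkage(squareform(dmat.to_numpy(dtype=float), checks=False),
                          method="average")
    root = hierarchy.to_tree(z)

    def newick(node, parent_height: float) -> str:
        # ultrametric convention: node height = merge distance / 2, so the
        # path between two leaves equals their cophenetic distance
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{length:.6f}"

    half = root.dist / 2.0
    nwk = f"({newick(root.left, half)},{newick(root.right, half)});"
    clusters = None
    if cut_threshold is not None:
        t = (1.0 - cut_threshold) if is_similarity else cut_threshold
        assign = hierarchy.fcluster(z, t=t, criterion="distance")
        clusters = pd.Series(assign, index=matrix.index, name="cluster")
    return nwk, clusters


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcoaResult:
    eigenvalues: np.ndarray          # descending, positive axes only
    coordinates: pd.DataFrame        # samples x axes
    pct_variance: np.ndarray         # percent per axis, sums to 100


def pcoa(dm: pd.DataFrame, eps: float = 1e-10) -> PcoaResult:
    """Classical principal coordinates analysis.

    Gower double-centering of -d^2/2, symmetric eigendecomposition,
    coordinates scaled by sqrt(eigenvalue) for positive eigenvalues only;
    axis variance percentages are taken over the positive-eigenvalue sum.
    """
    _check_distance(dm)
    d = dm.to_numpy(dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(1.0, abs(vals[0])) if n else vals > eps
    if not np.any(pos):
        coords = pd.DataFrame(np.zeros((n, 1)), index=dm.index, columns=["PCo1"])
        return PcoaResult(np.zeros(1), coords, np.zeros(1))
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    coords = vecs_p * np.sqrt(vals_p)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    pct = 100.0 * vals_p / vals_p.sum()
    return PcoaResult(vals_p, pd.DataFrame(coords, index=dm.index, columns=cols), pct)


# ---------------------------------------------------------------------------
# PHYLIP-style output
# ---------------------------------------------------------------------------

def write_square_phylip(dm: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in dm.iterrows():
            name = str(label)[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
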