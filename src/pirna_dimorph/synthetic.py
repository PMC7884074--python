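"""Synthetic germline-genomics data with known truth.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* one toy chromosome IV (default 8 Mb, an ~1:2 scale model of the real
  17.5 Mb chromosome) carrying two piRNA clusters in the same proportions as
  the real small (4.5-7 Mb) and big (13.5-17.2 Mb) clusters;
* 21 nt Type I piRNA loci with a 5' U and an 8 nt core motif (NNGTTTCA)
  planted upstream, its last base ``motif_gap`` bp before the piRNA 5' nt;
  male loci carry a 5' C on the motif (CNGTTTCA) with probability ``c_bias``;
* sex-biased negative-binomial locus counts across spermatogenesis and
  oogenesis samples, plus 22G-like antisense background reads and a
  constant-expression "U18-like" normalizer feature;
* IP/input ChIP fragment pileups whose occupancy at male loci depends on
  genotype (``tagged`` binds male loci; ``no_tag`` and ``degron`` do not);
* no-tag / tagged IP-MS peptide-count tables with planted enrichment factors.

Every draw comes from one ``numpy.random.default_rng(seed)``, so identical
seeds and parameters give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CHROM, DEFAULT_CHROM_LEN, DEFAULT_CLUSTERS
from .genome import Genome, revcomp
from .intervals import GenomicInterval

GENOTYPES = ("tagged", "no_tag", "degron")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: default enrichment factors for the IP-MS simulation: a SNAPc-like bait
#: complex plus true interactors over a field of unenriched proteins
DEFAULT_INTERACTORS = {
    "SNPC-4": 20.0,
    "SNPC-1.3": 12.0,
    "SNPC-1.2": 6.0,
    "SNPC-3.1": 5.0,
    "SNPC-3.2": 5.0,
    "SNPC-3.3": 4.0,
}


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    genome: Genome
    loci: pd.DataFrame          # id chrom start end strand sex_class motif_* ...
    expression: pd.DataFrame    # feature x condition expected counts
    occupancy: pd.DataFrame     # locus x genotype in [0, 1]
    dispersion: float
    interactors: Dict[str, float]
    control_feature: Dict
    params: Dict = field(default_factory=dict)

    def count_features(self) -> pd.DataFrame:
        """Loci plus the constant normalizer feature, for counting."""
        ctrl = pd.DataFrame([{
            "id": self.control_feature["id"],
            "chrom": self.control_feature["chrom"],
            "start": self.control_feature["start"],
            "end": self.control_feature["end"],
            "strand": self.control_feature["strand"],
            "sex_class": "unassigned",
        }])
        cols = ["id", "chrom", "start", "end", "strand", "sex_class"]
        return pd.concat([self.loci[cols], ctrl], ignore_index=True)

    def validate(self) -> None:
        """Check the planted loci satisfy their own invariants."""
        for row in self.loci.itertuples(index=False):
            if row.end - row.start != 21:
                raise AssertionError(f"{row.id}: length != 21")
            seq = self.genome.fetch(row.chrom, row.start, row.end)
            if row.strand == "-":
                seq = revcomp(seq)
            if seq[0] != "T":
                raise AssertionError(f"{row.id}: 5' nt is {seq[0]}, not T (U)")
            word = self.genome.fetch(row.chrom, row.motif_start, row.motif_start + 8)
            if row.strand == "-":
                word = revcomp(word)
            if word[2:] != "GTTTCA":
                raise AssertionError(f"{row.id}: core motif broken ({word})")
        occ = self.occupancy
        male = self.loci.set_index("id")["sex_class"] == "male"
        for g in ("no_tag", "degron"):
            if g in occ.columns and occ[g].abs().sum() > 0:
                raise AssertionError(f"occupancy must be 0 under {g!r}")
        if (self.expression <= 0).any().any():
            raise AssertionError("all expression means must be > 0")
        if not (occ.loc[~male.reindex(occ.index, fill_value=False), "tagged"] == 0).all():
            raise AssertionError("tagged occupancy must be confined to male loci")


def _plant(arr: np.ndarray, pos: int, word: str, strand: str) -> None:
    """Write ``word`` (given 5'->3' on ``strand``) into the index array."""
    if strand == "-":
        word = revcomp(word)
    for i, b in enumerate(word):
        arr[pos + i] = _BASE2IDX[b]


def build_toy_genome(
    n_male: int = 600,
    n_female: int = 300,
    n_ne: int = 600,
    chrom: str = DEFAULT_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    cluster_intervals: Sequence[GenomicInterval] = DEFAULT_CLUSTERS,
    motif_gap: int = 2,
    c_bias: float = 0.95,
    dup_fraction: float = 0.0,
    base_mean: float = 200.0,
    male_fc: float = 2.5,
    female_fc: float = 2.0,
    dispersion: float = 0.05,
    u18_mean: float = 1000.0,
    seed: int = 0,
) -> Tuple[Genome, SimTruth]:
    """Build the toy genome and its truth tables.

    Loci are laid on an evenly spaced grid of slots inside the clusters with
    uniform jitter inside each slot, which guarantees non-overlap and keeps
    each locus's 60 nt upstream window free of its neighbours.  Classes are
    shuffled across slots so male/female/NE loci interleave spatially, as on
    the real chromosome.
    """
    rng = np.random.default_rng(seed)
    n_total = n_male + n_female + n_ne
    clusters = list(cluster_intervals)
    for iv in clusters:
        if iv.chrom != chrom or iv.end > chrom_len:
            raise ValueError("clusters must fit on the single toy chromosome")
    cluster_lens = np.array([len(iv) for iv in clusters], dtype=float)
    # loci per cluster, proportional to cluster length
    alloc = np.floor(cluster_lens / cluster_lens.sum() * n_total).astype(int)
    alloc[0] += n_total - alloc.sum()
    footprint = 21 + motif_gap + 8 + 60  # locus + motif + free upstream margin
    for iv, k in zip(clusters, alloc):
        if k > 0 and len(iv) // k < footprint + 10:
            need = k * (footprint + 10)
            raise ValueError(
                f"cannot pack {k} loci into {iv.chrom}:{iv.start}-{iv.end}; "
                f"needs >= {need} bp of cluster"
            )

    arr = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)

    # slot grid with jitter
    starts: List[int] = []
    for iv, k in zip(clusters, alloc):
        if k == 0:
            continue
        slot = len(iv) // k
        jitter = rng.integers(0, max(1, slot - footprint), size=k)
        starts.extend(int(iv.start + i * slot + footprint + j)
                      for i, j in enumerate(jitter))
    starts = sorted(starts)

    classes = np.array(["male"] * n_male + ["female"] * n_female + ["NE"] * n_ne)
    rng.shuffle(classes)
    strands = np.where(rng.random(n_total) < 0.5, "+", "-")

    rows = []
    seen_21mers: Dict[str, int] = {}
    for i, (p, cls, strand) in enumerate(zip(starts, classes, strands)):
        # mature 21-mer: 5' U, random body; retry on (vanishingly rare) clash
        for _ in range(50):
            body = "".join("ACGT"[b] for b in rng.integers(0, 4, size=20))
            mer = "T" + body
            if mer not in seen_21mers:
                break
        else:  # pragma: no cover - 50 collisions in a row is impossible in practice
            raise RuntimeError("could not draw a unique 21-mer")
        seen_21mers[mer] = i
        _plant(arr, p, mer, strand)

        # core motif NNGTTTCA, last base motif_gap bp upstream of the 5' nt
        if cls == "male" and rng.random() < c_bias:
            n1 = "C"
        else:
            n1 = "ACGT"[rng.integers(0, 4)]
        n2 = "ACGT"[rng.integers(0, 4)]
        word = n1 + n2 + "GTTTCA"
        if strand == "+":
            motif_start = p - motif_gap - 8
        else:
            motif_start = p + 21 + motif_gap
        _plant(arr, motif_start, word, strand)

        rows.append({
            "id": f"21UR-sim{i:04d}", "chrom": chrom, "start": p,
            "end": p + 21, "strand": strand, "sex_class": cls,
            "pirna_type": "I", "sequence": mer,
            "motif_start": motif_start,
            "motif_offset": -(8 + motif_gap),
            "motif_n1": n1,
            "duplicated": False,
        })
    loci = pd.DataFrame(rows)

    # optional exact duplicates outside the clusters (multi-mapper fodder)
    if dup_fraction > 0:
        n_dup = int(round(dup_fraction * n_total))
        dup_idx = rng.choice(n_total, size=n_dup, replace=False)
        gap_regions = _intercluster_gaps(chrom_len, clusters)
        for j, li in enumerate(sorted(dup_idx)):
            region = gap_regions[j % len(gap_regions)]
            pos = int(rng.integers(region[0] + 100, region[1] - 100))
            _plant(arr, pos, loci.at[li, "sequence"], "+")
            loci.at[li, "duplicated"] = True

    # constant-expression normalizer feature, intergenic
    u18_pos = clusters[0].start // 2
    u18 = {"id": "U18", "chrom": chrom, "start": u18_pos,
           "end": u18_pos + 18, "strand": "+", "mean": u18_mean}

    seq = _BASES[arr].tobytes().decode("ascii")
    genome = Genome({chrom: seq})

    expr = pd.DataFrame(index=loci["id"],
                        columns=["spermatogenesis", "oogenesis"],
                        dtype=float)
    expr["spermatogenesis"] = base_mean
    expr["oogenesis"] = base_mean
    expr.loc[loci.set_index("id")["sex_class"] == "male", "spermatogenesis"] = (
        base_mean * male_fc)
    expr.loc[loci.set_index("id")["sex_class"] == "female", "oogenesis"] = (
        base_mean * female_fc)
    expr.loc["U18"] = [u18_mean, u18_mean]

    occ = pd.DataFrame(0.0, index=loci["id"], columns=list(GENOTYPES))
    occ.loc[loci.set_index("id")["sex_class"] == "male", "tagged"] = 1.0

    truth = SimTruth(
        genome=genome, loci=loci, expression=expr, occupancy=occ,
        dispersion=dispersion, interactors=dict(DEFAULT_INTERACTORS),
        control_feature=u18,
        params={
            "n_male": n_male, "n_female": n_female, "n_ne": n_ne,
            "chrom": chrom, "chrom_len": chrom_len,
            "cluster_intervals": [[iv.chrom, int(iv.start), int(iv.end)]
                                  for iv in clusters],
            "motif_gap": motif_gap, "c_bias": c_bias,
            "dup_fraction": dup_fraction, "base_mean": base_mean,
            "male_fc": male_fc, "female_fc": female_fc,
            "dispersion": dispersion, "seed": seed,
        },
    )
    return genome, truth


def _intercluster_gaps(chrom_len: int, clusters) -> List[Tuple[int, int]]:
    bounds = [0]
    for iv in sorted(clusters, key=lambda v: v.start):
        bounds.extend([iv.start, iv.end])
    bounds.append(chrom_len)
    gaps = []
    for a, b in zip(bounds[::2], bounds[1::2]):
        if b - a > 1000:
            gaps.append((a, b))
    return gaps


# ---------------------------------------------------------------------------
# truth serialization (lossless: every simulated dataset is reproducible
# from the saved parameters and a seed)
# ---------------------------------------------------------------------------

def save_truth(truth: SimTruth, out_dir) -> None:
    import os
    import yaml
    os.makedirs(out_dir, exist_ok=True)
    truth.genome.to_fasta(os.path.join(out_dir, "genome.fa"))
    truth.loci.to_csv(os.path.join(out_dir, "truth_loci.tsv"),
                      sep="\t", index=False)
    truth.expression.to_csv(os.path.join(out_dir, "truth_expression.tsv"),
                            sep="\t")
    truth.occupancy.to_csv(os.path.join(out_dir, "truth_occupancy.tsv"),
                           sep="\t")
    meta = dict(truth.params)
    meta["dispersion"] = truth.dispersion
    meta["interactors"] = truth.interactors
    meta["control_feature"] = truth.control_feature
    with open(os.path.join(out_dir, "truth_params.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_truth(out_dir) -> SimTruth:
    import os
    import yaml
    genome = Genome.from_fasta(os.path.join(out_dir, "genome.fa"))
    loci = pd.read_csv(os.path.join(out_dir, "truth_loci.tsv"), sep="\t")
    expression = pd.read_csv(os.path.join(out_dir, "truth_expression.tsv"),
                             sep="\t", index_col=0)
    occupancy = pd.read_csv(os.path.join(out_dir, "truth_occupancy.tsv"),
                            sep="\t", index_col=0)
    with open(os.path.join(out_dir, "truth_params.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return SimTruth(
        genome=genome, loci=loci, expression=expression, occupancy=occupancy,
        dispersion=float(meta.pop("dispersion")),
        interactors=meta.pop("interactors"),
        control_feature=meta.pop("control_feature"),
        params=meta,
    )


# ---------------------------------------------------------------------------
# small RNA-seq
# ---------------------------------------------------------------------------

def nb_counts(mean: np.ndarray, dispersion: float,
              rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with variance mu + dispersion * mu^2
    (dispersion 0 degenerates to Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean))


def simulate_counts(mean_matrix: pd.DataFrame, dispersion: float,
                    seed: int) -> pd.DataFrame:
    """NB count matrix (features x samples) from a matrix of expected counts."""
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(
        nb_counts(mean_matrix.to_numpy(dtype=float), dispersion, rng),
        index=mean_matrix.index, columns=mean_matrix.columns,
    )
    return out


def default_smallrna_design(n_rep: int = 3) -> pd.DataFrame:
    rows = []
    for cond in ("spermatogenesis", "oogenesis"):
        for r in range(1, n_rep + 1):
            rows.append({
                "sample_id": f"{cond[:3]}_{r}", "condition": cond,
                "genotype": "wild_type", "assay": "smallRNA", "replicate": r,
            })
    return pd.DataFrame(rows)


def simulate_smallrna(
    truth: SimTruth,
    design: pd.DataFrame,
    seed: int = 0,
    bg_fraction: float = 0.3,
    scale_range: Tuple[float, float] = (0.7, 1.3),
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame, pd.Series]:
    """Simulate small RNA-seq reads per sample.

    Per locus and sample a count is drawn NB(mean x library scale,
    dispersion); that many 21 nt reads sit exactly on the locus (sense).
    Background reads make up ``bg_fraction`` of each library: two thirds are
    22 nt 5'-G antisense "22G-like" reads over piRNA loci, one third random
    16-30 nt reads scattered over the chromosome.  Returns
    ``(reads per sample, true count matrix, library scales)``.
    """
    design = design[design["assay"] == "smallRNA"] if "assay" in design else design
    if design.groupby("condition")["sample_id"].count().min() < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    samples = list(design["sample_id"])
    scales = pd.Series(
        rng.uniform(scale_range[0], scale_range[1], size=len(samples)),
        index=samples, name="scale",
    )

    loci = truth.loci
    chrom = truth.params["chrom"]
    chrom_len = truth.params["chrom_len"]
    u18 = truth.control_feature
    feat_ids = list(loci["id"]) + [u18["id"]]
    counts = pd.DataFrame(0.0, index=feat_ids, columns=samples)

    l_start = loci["start"].to_numpy()
    l_end = loci["end"].to_numpy()
    l_strand = loci["strand"].to_numpy()
    l_nhits = np.where(loci["duplicated"].to_numpy(), 2, 1)

    reads_by_sample: Dict[str, pd.DataFrame] = {}
    cond_of = dict(zip(design["sample_id"], design["condition"]))
    for sid in samples:
        mu = truth.expression.loc[feat_ids, cond_of[sid]].to_numpy() * scales[sid]
        k = nb_counts(mu, truth.dispersion, rng)
        counts[sid] = k
        k_loci, k_u18 = k[:-1], int(k[-1])

        idx = np.repeat(np.arange(len(loci)), k_loci)
        sig = pd.DataFrame({
            "chrom": chrom,
            "start": l_start[idx],
            "end": l_end[idx],
            "strand": l_strand[idx],
            "n_hits": l_nhits[idx],
            "first_nt": "T",
        })
        n_sig = len(sig) + k_u18
        n_bg = int(round(n_sig * bg_fraction / (1.0 - bg_fraction)))
        n_22g = (2 * n_bg) // 3
        n_other = n_bg - n_22g

        # 22G-like: antisense over random piRNA loci
        li = rng.integers(0, len(loci), size=n_22g)
        g_start = l_start[li] - rng.integers(0, 2, size=n_22g)
        g22 = pd.DataFrame({
            "chrom": chrom,
            "start": g_start,
            "end": g_start + 22,
            "strand": np.where(l_strand[li] == "+", "-", "+"),
            "n_hits": 1,
            "first_nt": "G",
        })
        # other background: random lengths/positions/strands
        lens = rng.integers(16, 31, size=n_other)
        pos = rng.integers(0, chrom_len - 31, size=n_other)
        other = pd.DataFrame({
            "chrom": chrom,
            "start": pos,
            "end": pos + lens,
            "strand": np.where(rng.random(n_other) < 0.5, "+", "-"),
            "n_hits": 1,
            "first_nt": np.array(list("ACGT"))[rng.integers(0, 4, size=n_other)],
        })
        u18_reads = pd.DataFrame({
            "chrom": chrom,
            "start": np.full(k_u18, u18["start"]),
            "end": np.full(k_u18, u18["start"] + 18),
            "strand": "+",
            "n_hits": 1,
            "first_nt": truth.genome.fetch(chrom, u18["start"], u18["start"] + 1),
        })
        frame = pd.concat([sig, u18_reads, g22, other], ignore_index=True)
        frame["weight"] = 1.0 / frame["n_hits"]
        reads_by_sample[sid] = frame

    return reads_by_sample, counts, scales


# ---------------------------------------------------------------------------
# ChIP
# ---------------------------------------------------------------------------

def simulate_chip(
    truth: SimTruth,
    genotype: str,
    depth: int,
    seed: int = 0,
    bound_fraction: float = 0.3,
    jitter_sd: float = 60.0,
    input_depth: Optional[int] = None,
    frag_len: int = 200,
    read_len: int = 50,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate IP and input ChIP reads for one genotype.

    Input fragments are uniform over the chromosome.  IP fragments are a
    mixture: fraction ``1 - bound_fraction`` uniform background, fraction
    ``bound_fraction`` centred on the planted core-motif midpoint of a locus
    drawn proportional to occupancy(genotype), with Gaussian jitter.  If the
    genotype has zero total occupancy (no-tag, degron) the whole library is
    background.  Fragments are ``frag_len`` bp; reads are the ``read_len`` bp
    5' end of each fragment on a random strand.  Input depth defaults to
    5 x IP depth: a deliberately deep input that stabilizes the ratio
    denominator at desk-scale sequencing depths (see docs/methods.md).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if genotype not in truth.occupancy.columns:
        raise ValueError(f"unknown genotype {genotype!r}")
    if input_depth is None:
        input_depth = 5 * depth
    rng = np.random.default_rng(seed)
    chrom = truth.params["chrom"]
    chrom_len = truth.params["chrom_len"]

    occ = truth.occupancy[genotype].to_numpy(dtype=float)
    total_occ = occ.sum()
    bound = rng.random(depth) < bound_fraction if total_occ > 0 else \
        np.zeros(depth, dtype=bool)
    n_bound = int(bound.sum())

    frag_start = np.empty(depth, dtype=np.int64)
    n_bg = depth - n_bound
    frag_start[~bound] = rng.integers(0, chrom_len - frag_len + 1, size=n_bg)
    if n_bound:
        mid = ((truth.loci["motif_start"].to_numpy() + 4)
               .astype(float))  # midpoint of the 8 bp motif
        li = rng.choice(len(occ), size=n_bound, p=occ / total_occ)
        centers = mid[li] + rng.normal(0.0, jitter_sd, size=n_bound)
        fs = np.round(centers - frag_len / 2).astype(np.int64)
        frag_start[bound] = np.clip(fs, 0, chrom_len - frag_len)

    def reads_from_fragments(fs: np.ndarray, gen: np.random.Generator
                             ) -> pd.DataFrame:
        fe = fs + frag_len
        minus = gen.random(len(fs)) < 0.5
        start = np.where(minus, fe - read_len, fs)
        return pd.DataFrame({
            "chrom": chrom,
            "start": start,
            "end": start + read_len,
            "strand": np.where(minus, "-", "+"),
            "weight": 1.0,
            "n_hits": 1,
        })

    ip = reads_from_fragments(frag_start, rng)
    inp_start = rng.integers(0, chrom_len - frag_len + 1, size=input_depth)
    inp = reads_from_fragments(inp_start, rng)
    return ip, inp


# ---------------------------------------------------------------------------
# IP-MS peptide counts
# ---------------------------------------------------------------------------

def simulate_peptides(
    interactors: Dict[str, float],
    n_proteins: int = 400,
    totals: int | Dict[str, int] = 1000,
    seed: int = 0,
    n_rep: int = 2,
    baseline_sd: float = 0.5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate no-tag control vs tagged IP spectral counts.

    Control counts are multinomial over a lognormal-jittered uniform
    baseline; IP counts multiply the baseline probabilities of interactor
    proteins by their enrichment factors and renormalize.  Returns
    ``(peptide table, sample sheet)``; column sums equal the requested totals.
    """
    if any(f <= 0 for f in interactors.values()):
        raise ValueError("enrichment factors must be > 0")
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    names = list(interactors) + [
        f"P{i:04d}" for i in range(n_proteins - len(interactors))
    ]
    baseline = rng.lognormal(0.0, baseline_sd, size=n_proteins)
    baseline /= baseline.sum()
    factors = np.ones(n_proteins)
    factors[: len(interactors)] = list(interactors.values())
    ip_p = baseline * factors
    ip_p /= ip_p.sum()

    samples = [f"IP_{r}" for r in range(1, n_rep + 1)] + \
              [f"ctrl_{r}" for r in range(1, n_rep + 1)]
    if isinstance(totals, int):
        totals = {s: totals for s in samples}
    cols = {}
    for s in samples:
        if totals[s] <= 0:
            raise ValueError("sample totals must be > 0")
        p = ip_p if s.startswith("IP_") else baseline
        cols[s] = rng.multinomial(totals[s], p)
    table = pd.DataFrame(cols, index=names)
    sheet = pd.DataFrame({
        "sample_id": samples,
        "condition": "spermatogenesis",
        "genotype": ["tagged"] * n_rep + ["no_tag"] * n_rep,
        "assay": ["IPMS_IP"] * n_rep + ["IPMS_control"] * n_rep,
        "replicate": list(range(1, n_rep + 1)) * 2,
    })
    return table, sheet
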