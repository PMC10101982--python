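"""Synthetic data generators for desk-scale pipeline runs.

The generators emulate the two kinds of input the analyses consume:

* circNC amplicons: a transcript is decapped, circularized and PCR-amplified
  across the 5'/3' junction, so the amplicon reads
  ``transcript[fwd_primer .. 3' end] + polyA + transcript[cap site .. rev_primer]``.
  :func:`simulate_circ_reads` builds such amplicons from a
  :class:`TranscriptModel` with heterogeneous cap-addition sites, 3' ends and
  polyA-tail lengths, sequences paired-end reads off them with uniform
  substitution errors, and emits a per-read ground-truth table.
* capture-enrichment counts: :func:`simulate_counts` draws gene x sample
  negative-binomial count matrices (var = mu + alpha * mu^2) in biological
  triplicate with a planted enriched gene subset at a known log2 fold change.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nadcapseq.errors import ConfigurationError

NUCLEOTIDES = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """A reference transcript with annotated cap-site and 3'-end distributions.

    Serves both as simulation ground truth and as the coordinate frame for
    junction calls. All coordinates are 0-based, half-open, on the sense
    strand; ``cap_site_dist_*`` and ``cleavage_site_dist`` are lists of
    ``(position, weight)`` pairs whose weights sum to 1. ``polya_len_params``
    is ``(mean, sd, min)`` of a truncated normal tail-length model.
    ``primer_fwd`` / ``primer_rev`` are transcript intervals: the forward
    primer sits near the 3' end of the CDS (start of the amplicon's 3'
    segment) and the reverse primer near the CDS start (end of the amplicon's
    5' segment).
    """

    gene_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    cap_site_dist_m7g: list[tuple[int, float]]
    cap_site_dist_nad: list[tuple[int, float]]
    cleavage_site_dist: list[tuple[int, float]]
    polya_len_params: tuple[float, float, int] = (30.0, 6.0, 12)
    primer_fwd: tuple[int, int] = (0, 0)
    primer_rev: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            raise ConfigurationError(
                f"{self.gene_id}: segment lengths do not sum to sequence length"
            )
        for name in ("cap_site_dist_m7g", "cap_site_dist_nad", "cleavage_site_dist"):
            dist = getattr(self, name)
            if dist:
                w = [x[1] for x in dist]
                if min(w) < 0 or not math.isclose(sum(w), 1.0, abs_tol=1e-9):
                    raise ConfigurationError(
                        f"{self.gene_id}: {name} weights must be >=0 and sum to 1"
                    )
        cap_positions = [p for p, _ in self.cap_site_dist_m7g + self.cap_site_dist_nad]
        cleave_positions = [p for p, _ in self.cleavage_site_dist]
        if cap_positions and cleave_positions:
            if max(cap_positions) >= min(cleave_positions):
                raise ConfigurationError(
                    f"{self.gene_id}: cap sites must precede cleavage sites"
                )
        if self.polya_len_params[2] < 0:
            raise ConfigurationError("polyA minimum length must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    def cap_dist(self, cap_type: str) -> list[tuple[int, float]]:
        if cap_type == "NAD":
            return self.cap_site_dist_nad
        if cap_type == "m7G":
            return self.cap_site_dist_m7g
        raise ConfigurationError(f"unknown cap type {cap_type!r}")


@dataclass
class CircReadTruth:
    """Ground truth for one simulated circNC read pair.

    ``left_a_ext`` / ``right_a_ext`` record how many reference A bases
    directly abut the planted polyA run (end of the 3' segment / start of
    the 5' segment): a templated A at the junction edge is absorbed into
    the maximal run, so these extensions are needed for exact
    boundary-attribution tests. ``junction_spanning`` is true when the
    merged amplicon read would contain the full run plus at least one
    flanking base on each side.
    """

    read_id: str
    cap_type: str
    true_cap_site: int
    true_3p_site: int
    true_polya_len: int
    n_errors: int
    left_a_ext: int = 0
    right_a_ext: int = 0
    junction_spanning: bool = True
    truncated: bool = False


@dataclass
class FastqRecord:
    """One sequencing read: id, bases, phred quality string."""

    read_id: str
    sequence: str
    quality: str


@dataclass
class CountSimConfig:
    """Configuration of the negative-binomial count simulator.

    ``dispersion`` is the NB alpha in var = mu + alpha * mu^2 (0 gives the
    Poisson limit). ``planted_enriched`` genes receive a capture:control
    mean ratio of ``2**planted_log2fc``. ``mean_expression_dist_params`` are
    (meanlog, sdlog) of the log-normal relative-expression model, rescaled
    so expected per-sample totals equal ``library_depth``.
    """

    n_genes: int
    replicates_per_condition: int = 3
    planted_enriched: frozenset = field(default_factory=frozenset)
    planted_log2fc: float = 2.0
    dispersion: float = 0.05
    mean_expression_dist_params: tuple[float, float] = (0.0, 1.0)
    library_depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ConfigurationError("need >=2 replicates per condition")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        universe = {f"g{i:05d}" for i in range(self.n_genes)}
        if not set(self.planted_enriched) <= universe:
            raise ConfigurationError("planted set must be a subset of the gene universe")


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

DEFAULT_LENGTH_PARAMS = {"utr5": (20, 100), "cds": (300, 900), "utr3": (50, 300)}


def _random_sequence(rng: np.random.Generator, length: int, max_run: int = 6) -> str:
    """IID ACGT sequence with A/T homopolymer runs capped at ``max_run``.

    Internal A runs of >=8 (or T runs, which become A runs on the reverse
    complement) would collide with the polyA junction filter, so the
    generator breaks them.
    """
    bases = list(rng.choice(NUCLEOTIDES, size=length))
    run = 1
    for i in range(1, length):
        if bases[i] == bases[i - 1]:
            run += 1
        else:
            run = 1
        if run > max_run and bases[i] in "AT":
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(len(choices))]
            run = 1
    return "".join(bases)


def _site_distribution(
    rng: np.random.Generator, lo: int, hi: int, n_sites: int
) -> list[tuple[int, float]]:
    """Pick ``n_sites`` distinct positions in [lo, hi) with Dirichlet weights,
    the first (predominant) site carrying the bulk of the mass."""
    n_sites = min(n_sites, hi - lo)
    positions = rng.choice(np.arange(lo, hi), size=n_sites, replace=False)
    raw = rng.dirichlet(np.ones(n_sites) * 0.6)
    order = np.argsort(raw)[::-1]
    weights = raw[order] / raw.sum()
    return [(int(p), float(w)) for p, w in zip(positions, weights)]


def generate_transcriptome(
    n_genes: int,
    length_params: dict | None = None,
    seed: int = 0,
    polya_len_params: tuple[float, float, int] = (30.0, 6.0, 12),
) -> list[TranscriptModel]:
    """Generate ``n_genes`` transcript models with cap-site heterogeneity.

    ``length_params`` maps segment name (utr5, cds, utr3) to an inclusive
    (min, max) length range. NAD and m7G cap-site distributions are drawn
    over the 5' UTR with distinct predominant sites; cleavage sites sit in
    the final 10 nt of the 3' UTR; primers flank the CDS as in a
    junction-spanning amplicon design.
    """
    params = dict(DEFAULT_LENGTH_PARAMS)
    if length_params:
        params.update(length_params)
    for name, (lo, hi) in params.items():
        if lo > hi or lo <= 0:
            raise ConfigurationError(f"invalid length range for {name}: ({lo}, {hi})")
    if n_genes < 0:
        raise ConfigurationError("n_genes must be >= 0")

    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_genes):
        utr5 = int(rng.integers(params["utr5"][0], params["utr5"][1] + 1))
        cds = int(rng.integers(params["cds"][0], params["cds"][1] + 1))
        utr3 = int(rng.integers(params["utr3"][0], params["utr3"][1] + 1))
        total = utr5 + cds + utr3
        seq = _random_sequence(rng, total)
        # cap sites live in the 5' UTR; keep NAD and m7G predominant sites distinct
        nad = _site_distribution(rng, 0, utr5, n_sites=3)
        m7g = _site_distribution(rng, 0, utr5, n_sites=3)
        if m7g[0][0] == nad[0][0] and utr5 > 3:
            shifted = (nad[0][0] + 2) % utr5
            m7g = [(shifted, m7g[0][1])] + [
                (p, w) for p, w in m7g[1:] if p != shifted
            ]
            renorm = sum(w for _, w in m7g)
            m7g = [(p, w / renorm) for p, w in m7g]
        cleave = _site_distribution(rng, total - 10, total, n_sites=2)
        fwd_start = utr5 + cds - 90
        model = TranscriptModel(
            gene_id=f"g{i:05d}",
            sequence=seq,
            utr5_len=utr5,
            cds_len=cds,
            utr3_len=utr3,
            cap_site_dist_m7g=m7g,
            cap_site_dist_nad=nad,
            cleavage_site_dist=cleave,
            polya_len_params=polya_len_params,
            primer_fwd=(fwd_start, fwd_start + 20),
            primer_rev=(utr5 + 60, utr5 + 80),
        )
        models.append(model)
    return models


def transcriptome_fasta(models: list[TranscriptModel]) -> str:
    """Reference FASTA text (60-column wrapped) for a list of models."""
    out = []
    for m in models:
        out.append(f">{m.gene_id}")
        for i in range(0, len(m.sequence), 60):
            out.append(m.sequence[i : i + 60])
    return "\n".join(out) + ("\n" if out else "")


def transcriptome_annotation(models: list[TranscriptModel]) -> pd.DataFrame:
    """Annotation table: segment lengths and primer coordinates per gene."""
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "utr5_len": [m.utr5_len for m in models],
            "cds_len": [m.cds_len for m in models],
            "utr3_len": [m.utr3_len for m in models],
            "primer_fwd_start": [m.primer_fwd[0] for m in models],
            "primer_fwd_end": [m.primer_fwd[1] for m in models],
            "primer_rev_start": [m.primer_rev[0] for m in models],
            "primer_rev_end": [m.primer_rev[1] for m in models],
        }
    )


# ---------------------------------------------------------------------------
# circNC amplicon reads
# ---------------------------------------------------------------------------


def _sample_site(rng: np.random.Generator, dist: list[tuple[int, float]]) -> int:
    positions = [p for p, _ in dist]
    weights = [w for _, w in dist]
    return int(positions[rng.choice(len(positions), p=weights)])


def _truncnorm_int(rng: np.random.Generator, mean: float, sd: float, lo: int) -> int:
    while True:
        x = int(round(rng.normal(mean, sd)))
        if x >= lo:
            return x


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    if error_rate == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [b for b in "ACGT" if b != base]
        arr[i] = choices[rng.integers(len(choices))].encode()
    return arr.tobytes().decode(), len(hits)


def simulate_circ_reads(
    model: TranscriptModel,
    n_reads: int,
    cap_type: str = "NAD",
    error_rate: float = 0.0,
    read_len: int = 250,
    seed: int = 0,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], list[CircReadTruth]]:
    """Simulate paired reads off circNC junction amplicons.

    Each amplicon is ``transcript[fwd_primer.start : 3' site] + A*L +
    transcript[cap_site : rev_primer.end]``; read 1 is its first
    ``read_len`` bases and read 2 the reverse complement of its last
    ``read_len`` bases, with uniform substitution errors at ``error_rate``
    per base. Truth rows carry the planted coordinates, the A extensions at
    the junction edges and a flag for amplicons too long for the pair to
    span the junction.
    """
    if not 0 <= error_rate < 1:
        raise ConfigurationError("error_rate must be in [0, 1)")
    dist = model.cap_dist(cap_type)
    if not dist:
        raise ConfigurationError(f"{model.gene_id}: empty {cap_type} cap-site distribution")
    if not model.cleavage_site_dist:
        raise ConfigurationError(f"{model.gene_id}: empty cleavage-site distribution")

    rng = np.random.default_rng(seed)
    mean, sd, lo = model.polya_len_params
    pairs: list[tuple[FastqRecord, FastqRecord]] = []
    truths: list[CircReadTruth] = []
    for i in range(n_reads):
        cap_site = _sample_site(rng, dist)
        site_3p = _sample_site(rng, model.cleavage_site_dist)
        polya_len = _truncnorm_int(rng, mean, sd, lo)
        seg3 = model.sequence[model.primer_fwd[0] : site_3p]
        seg5 = model.sequence[cap_site : model.primer_rev[1]]
        amplicon = seg3 + "A" * polya_len + seg5

        left_ext = len(seg3) - len(seg3.rstrip("A"))
        right_ext = len(seg5) - len(seg5.lstrip("A"))

        run_start = len(seg3) - left_ext
        run_end = len(seg3) + polya_len + right_ext
        # can the pair reconstruct the junction? merged coverage is the
        # union of the first and last read_len bases of the amplicon
        covered = (
            len(amplicon) <= 2 * read_len
            and run_start >= 1
            and run_end <= len(amplicon) - 1
        )
        truncated = len(amplicon) > 2 * read_len

        r1_seq = amplicon[:read_len]
        r2_seq = revcomp(amplicon[-read_len:])
        r1_seq, e1 = _apply_errors(rng, r1_seq, error_rate)
        r2_seq, e2 = _apply_errors(rng, r2_seq, error_rate)
        read_id = f"{model.gene_id}:{cap_type}:{i:06d}"
        qual1 = "I" * len(r1_seq)
        qual2 = "I" * len(r2_seq)
        pairs.append(
            (
                FastqRecord(read_id + "/1", r1_seq, qual1),
                FastqRecord(read_id + "/2", r2_seq, qual2),
            )
        )
        truths.append(
            CircReadTruth(
                read_id=read_id,
                cap_type=cap_type,
                true_cap_site=cap_site,
                true_3p_site=site_3p,
                true_polya_len=polya_len,
                n_errors=e1 + e2,
                left_a_ext=left_ext,
                right_a_ext=right_ext,
                junction_spanning=covered,
                truncated=truncated,
            )
        )
    return pairs, truths


def truth_table(truths: list[CircReadTruth]) -> pd.DataFrame:
    """Truth rows as a DataFrame (one row per read pair)."""
    return pd.DataFrame([t.__dict__ for t in truths])


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def simulate_counts(cfg: CountSimConfig):
    """Simulate a capture vs. RNA-seq count matrix with planted enrichment.

    Returns ``(CountMatrix, truth)`` where truth marks each gene's planted
    status and true log2 fold change. Control (rnaseq) gene means follow a
    log-normal rescaled to ``library_depth``; capture (nadcappro) means are
    multiplied by ``2**planted_log2fc`` for planted genes; counts are NB
    with var = mu + alpha * mu^2 (Poisson when alpha == 0).
    """
    from nadcapseq.enrichment import CountMatrix

    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    gene_lengths = rng.integers(500, 3001, size=cfg.n_genes)

    meanlog, sdlog = cfg.mean_expression_dist_params
    rel = rng.lognormal(meanlog, sdlog, size=cfg.n_genes)
    base_mu = rel / rel.sum() * cfg.library_depth

    fold = np.ones(cfg.n_genes)
    planted_mask = np.array([g in cfg.planted_enriched for g in gene_ids])
    fold[planted_mask] = 2.0 ** cfg.planted_log2fc

    nrep = cfg.replicates_per_condition
    cols, sample_ids, conditions = [], [], []
    for rep in range(nrep):
        cols.append(_nb_draw(rng, base_mu, cfg.dispersion))
        sample_ids.append(f"rnaseq_{rep + 1}")
        conditions.append("rnaseq")
    for rep in range(nrep):
        cols.append(_nb_draw(rng, base_mu * fold, cfg.dispersion))
        sample_ids.append(f"nadcappro_{rep + 1}")
        conditions.append("nadcappro")

    counts = np.column_stack(cols)
    matrix = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        conditions=conditions,
        counts=counts,
        gene_lengths=gene_lengths.astype(int),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "enriched": planted_mask,
            "true_log2fc": np.where(planted_mask, cfg.planted_log2fc, 0.0),
            "base_mean": base_mu,
        }
    )
    return matrix, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) sample; Poisson in the alpha -> 0 limit."""
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# gene sets with forced overlap
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    universe_size: int, n1: int, n2: int, forced_overlap: int, seed: int = 0
) -> tuple[set, set, list]:
    """Two gene sets over a labeled universe with an exact intersection size.

    Returns ``(A, B, universe)`` with |A| = n1, |B| = n2 and
    |A & B| = forced_overlap exactly.
    """
    if n1 > universe_size or n2 > universe_size:
        raise ConfigurationError("set sizes exceed universe size")
    if forced_overlap > min(n1, n2):
        raise ConfigurationError("forced overlap exceeds smaller set size")
    if n1 + n2 - forced_overlap > universe_size:
        raise ConfigurationError(
            "universe too small for the requested disjointness "
            f"({n1} + {n2} - {forced_overlap} > {universe_size})"
        )
    rng = np.random.default_rng(seed)
    universe = [f"g{i:05d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    shared = order[:forced_overlap]
    only_a = order[forced_overlap : n1]
    only_b = order[n1 : n1 + (n2 - forced_overlap)]
    set_a = {universe[i] for i in np.concatenate([shared, only_a]).astype(int)}
    set_b = {universe[i] for i in np.concatenate([shared, only_b]).astype(int)}
    return set_a, set_b, universe
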