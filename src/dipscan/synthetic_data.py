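"""Synthetic dDIP-seq data generation.

Everything the pipeline consumes can be generated here with known ground
truth: a reference coding sequence, per-site trafficking probabilities for
each inserted domain, a MuA-style insertion library with 5-bp target-site
duplications and a 5'-depressed positional bias, sorted-pool (surface
expressed vs not) read counts, junction read pairs, residue-level protein
property tables, and DiBAC-style flow-cytometry event tables.

Site classes encode the three observed permissibility regimes plus an
intermediate class: *permissive* sites traffic regardless of the inserted
domain, *scaffold* sites tolerate nothing, *differential* sites traffic for
one domain but not another, and *intermediate* sites sit between. Ground
truth is indexed by insertion slot ``aa_pos = nt_pos // 3`` (0 = before
residue 1), matching the caller's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import zlib

import numpy as np
from Bio.Seq import Seq

from .insertion_calling import InsertionCountTable, revcomp, DEFAULT_MIN_ANCHOR

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# one fixed codon per amino acid, used when reverse-translating linkers and
# synthetic insert sequences
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

SITE_CLASSES = ("permissive", "scaffold", "differential", "intermediate")

# default trafficking probabilities per site class; differential sites get
# P_HIGH for one of the first two domains and P_LOW for the other
DEFAULT_P_SE = {"permissive": 0.8, "scaffold": 0.05, "intermediate": 0.45}
DIFFERENTIAL_P_HIGH = 0.7
DIFFERENTIAL_P_LOW = 0.1
DIFFERENTIAL_P_OTHER = 0.4

# class mix of the simulated gene: mirrors a channel with large scaffold
# (membrane-embedded) stretches, permissive termini/loops and a modest number
# of differentially permissive sites (40 of 435 slots under the default gene)
DEFAULT_CLASS_FRACTIONS = {
    "permissive": 140 / 435,
    "scaffold": 185 / 435,
    "differential": 40 / 435,
    "intermediate": 70 / 435,
}


def reverse_translate(aa: str) -> str:
    return "".join(_CODON_OF[a] for a in aa)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGene:
    """A coding sequence; starts with ATG, ends with a stop codon, no internal
    in-frame stops."""

    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if set(self.cds) - set(_BASES):
            raise ValueError("CDS alphabet must be A/C/G/T")
        if self.n_residues < 10:
            raise ValueError("reference must encode at least 10 residues")

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3


@dataclass(frozen=True)
class DomainCassette:
    """An insertable domain with its flanking linkers (Ala-Ser on the N side,
    Gly-Ser-Ala on the C side by default)."""

    name: str
    insert_aa: str
    insert_nt: str
    linker_n: str = "AS"
    linker_c: str = "GSA"

    def __post_init__(self) -> None:
        if str(Seq(self.insert_nt).translate()) != self.insert_aa:
            raise ValueError("insert_nt does not translate to insert_aa")

    @classmethod
    def from_aa(cls, name: str, insert_aa: str, linker_n: str = "AS",
                linker_c: str = "GSA") -> "DomainCassette":
        return cls(name, insert_aa, reverse_translate(insert_aa),
                   linker_n=linker_n, linker_c=linker_c)

    def full_nt(self) -> str:
        """Linker-flanked cassette nucleotide sequence as inserted."""
        return (reverse_translate(self.linker_n) + self.insert_nt
                + reverse_translate(self.linker_c))


@dataclass(frozen=True)
class GroundTruthSite:
    """Ground truth for one insertion slot."""

    aa_pos: int
    site_class: str
    p_se: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        for d, p in self.p_se.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_se[{d!r}]={p} outside [0,1]")


def default_domains(seed: int = 20190117) -> list[DomainCassette]:
    """Two synthetic stand-in cassettes of realistic small-domain size
    (~80 aa, the scale of a PDZ or Cib81 domain)."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for name in ("PDZ", "Cib81"):
        aa = "".join(rng.choice(list(aas), size=80))
        out.append(DomainCassette.from_aa(name, aa))
    return out


@dataclass
class SimulationConfig:
    """Parameters of one simulated dDIP-seq study.

    ``bias_amplitude``/``bias_length_scale`` shape the MuA positional bias
    w(p) = 1 - b*exp(-p/lambda) (5'-depressed coverage); ``n_variants`` is the
    number of transposition events in the library (cells carrying each variant
    scale with its library count); ``depth_per_pool`` is sequencing reads per
    sorted pool.
    """

    seed: int = 0
    n_variants: int = 1_000_000
    depth_per_pool: int = 200_000
    n_replicates: int = 3
    bias_amplitude: float = 0.8
    bias_length_scale: float = 150.0
    read_length: int = 100
    error_rate: float = 0.0
    domains: list[DomainCassette] = field(default_factory=default_domains)

    def __post_init__(self) -> None:
        if self.depth_per_pool < 1:
            raise ValueError("depth_per_pool must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_reference(n_residues: int, seed: int) -> ReferenceGene:
    """Random CDS: ATG, ``n_residues - 2`` random non-stop codons, TAA."""
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    sense = [c for c in codons if c not in STOP_CODONS]
    body = rng.choice(sense, size=n_residues - 2)
    return ReferenceGene("ATG" + "".join(body) + "TAA")


def scoreable_positions(reference: ReferenceGene) -> np.ndarray:
    """Insertion slots reachable by a productive insertion: nt_pos in
    {0, 3, ...} with nt_pos <= len(cds) - 5."""
    max_nt = len(reference.cds) - 5
    return np.arange(0, max_nt // 3 + 1)


def simulate_truth(reference: ReferenceGene,
                   domains: Sequence[DomainCassette] | Sequence[str] | None = None,
                   class_fractions: Mapping[str, float] | None = None,
                   p_se_table: Mapping[str, Mapping[str, float] | float] | None = None,
                   seed: int = 0) -> list[GroundTruthSite]:
    """Assign a site class and per-domain trafficking probability to every
    scoreable insertion slot.

    Class counts follow ``class_fractions`` (largest-remainder rounding, then
    a seeded shuffle). Differential sites alternate which of the first two
    domains traffics (P=0.7 vs P=0.1); further domains get an intermediate
    0.4. ``p_se_table`` overrides the per-class probabilities with either a
    scalar (all domains) or a domain->p mapping.
    """
    if domains is None:
        domains = default_domains()
    names = [d.name if isinstance(d, DomainCassette) else str(d) for d in domains]
    if len(names) == 0:
        raise ValueError("at least one domain required")
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None
                     else class_fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1 (got {total})")
    slots = scoreable_positions(reference)
    n = len(slots)
    classes = sorted(fractions)  # stable order for rounding
    raw = {c: fractions[c] * n for c in classes}
    counts = {c: int(np.floor(raw[c])) for c in classes}
    remainder = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - np.floor(raw[c]),
                    reverse=True)[:remainder]:
        counts[c] += 1
    labels = np.concatenate([np.full(counts[c], i)
                             for i, c in enumerate(classes)]) if n else np.array([])
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    def class_p(site_class: str, diff_index: int) -> dict[str, float]:
        if p_se_table is not None and site_class in p_se_table:
            entry = p_se_table[site_class]
            if isinstance(entry, Mapping):
                return {d: float(entry[d]) for d in names}
            return {d: float(entry) for d in names}
        if site_class == "differential":
            out = {d: DIFFERENTIAL_P_OTHER for d in names}
            hi, lo = (0, 1) if diff_index % 2 == 0 else (1, 0)
            out[names[hi]] = DIFFERENTIAL_P_HIGH
            if len(names) > 1:
                out[names[lo]] = DIFFERENTIAL_P_LOW
            return out
        return {d: DEFAULT_P_SE[site_class] for d in names}

    sites = []
    diff_seen = 0
    for slot, lab in zip(slots, labels):
        site_class = classes[int(lab)]
        di = diff_seen
        if site_class == "differential":
            diff_seen += 1
        sites.append(GroundTruthSite(int(slot), site_class,
                                     class_p(site_class, di)))
    return sites


def position_weights(length: int, bias_amplitude: float,
                     bias_length_scale: float) -> np.ndarray:
    """Unnormalised MuA insertion weight w(p) = 1 - b*exp(-p/lambda) over
    nt positions 0 .. length-1."""
    p = np.arange(length)
    return 1.0 - bias_amplitude * np.exp(-p / bias_length_scale)


def simulate_library(reference: ReferenceGene, config: SimulationConfig):
    """Draw the insertion library: a DataFrame (nt_pos, orientation, count).

    Positions 0..len(cds)-5 are drawn with the 5'-depressed weight,
    orientation uniform, counts multinomial with ``n_variants`` trials.
    Zero-count variants are dropped.
    """
    import pandas as pd

    n_pos = len(reference.cds) - 4  # nt_pos in 0 .. len-5 inclusive
    w = position_weights(n_pos, config.bias_amplitude, config.bias_length_scale)
    probs = np.repeat(w / w.sum() / 2.0, 2)
    rng = np.random.default_rng([config.seed, 101])
    if config.n_variants == 0:
        counts = np.zeros(2 * n_pos, dtype=np.int64)
    else:
        counts = rng.multinomial(config.n_variants, probs)
    nt_pos = np.repeat(np.arange(n_pos), 2)
    orientation = np.tile(np.array(["forward", "reverse"]), n_pos)
    df = pd.DataFrame({"nt_pos": nt_pos, "orientation": orientation,
                       "count": counts})
    return df[df["count"] > 0].reset_index(drop=True)


def _domain_tag(domain: str) -> int:
    return zlib.crc32(domain.encode())


def simulate_sort_counts(library, truth: Sequence[GroundTruthSite],
                         domain: str, config: SimulationConfig,
                         replicate_seed: int,
                         ) -> tuple[InsertionCountTable, InsertionCountTable]:
    """FACS + sequencing of one replicate of one domain library.

    Each cell carrying a productive variant (forward, in-frame) surfaces with
    probability ``p_se[site_class, domain]``; sequencing draws
    ``depth_per_pool`` reads multinomially over each pool's cells. Returns
    (SE, NSE) count tables; a pool with no cells yields an all-zero table.
    """
    p_map = {}
    for s in truth:
        if domain not in s.p_se:
            raise KeyError(f"domain {domain!r} missing from ground-truth p_se")
        p_map[s.aa_pos] = s.p_se[domain]
    prod = library[(library["orientation"] == "forward")
                   & (library["nt_pos"] % 3 == 0)]
    aa = (prod["nt_pos"].to_numpy() // 3).astype(int)
    cells = prod["count"].to_numpy()
    p = np.array([p_map[a] for a in aa])
    rng = np.random.default_rng(
        [config.seed, replicate_seed, _domain_tag(domain)])
    se_cells = rng.binomial(cells, p)
    nse_cells = cells - se_cells

    n_slots = max(s.aa_pos for s in truth) + 1

    def pool_reads(pool_cells: np.ndarray, pool: str) -> InsertionCountTable:
        counts = np.zeros(n_slots, dtype=np.int64)
        total = pool_cells.sum()
        if total > 0:
            reads = rng.multinomial(config.depth_per_pool, pool_cells / total)
            np.add.at(counts, aa, reads)
        return InsertionCountTable(counts, sample_id=f"{domain}_r{replicate_seed}",
                                   pool=pool, replicate=replicate_seed,
                                   domain=domain)

    return pool_reads(se_cells, "SE"), pool_reads(nse_cells, "NSE")


def simulate_reads(library, reference: ReferenceGene,
                   cassette: DomainCassette, config: SimulationConfig,
                   ) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Paired junction reads, one pair per library count unit.

    R1 reads across the upstream junction on the top strand, R2 is the
    reverse complement of a window across the downstream junction. Read ids
    encode the ground truth (``var{i}|nt{p}|{orientation}|{k}``) for test
    oracles. Substitution errors at ``config.error_rate``.
    """
    if config.read_length < 2 * DEFAULT_MIN_ANCHOR:
        raise ValueError(
            f"read_length must be >= {2 * DEFAULT_MIN_ANCHOR} to leave two "
            f"anchors")
    cds = reference.cds
    rl = config.read_length
    half = rl // 2
    rng = np.random.default_rng([config.seed, 202])
    cass_fwd = cassette.full_nt()
    pairs = []
    var_i = 0
    for row in library.itertuples(index=False):
        p, orient, count = int(row.nt_pos), row.orientation, int(row.count)
        cass = cass_fwd if orient == "forward" else revcomp(cass_fwd)
        variant = cds[: p + 5] + cass + cds[p:]
        j1 = p + 5
        j2 = p + 5 + len(cass)
        s1 = min(max(0, j1 - half), len(variant) - rl)
        s2 = min(max(0, j2 - half), len(variant) - rl)
        for k in range(count):
            r1 = variant[s1: s1 + rl]
            r2 = revcomp(variant[s2: s2 + rl])
            if config.error_rate > 0:
                r1 = _add_errors(r1, config.error_rate, rng)
                r2 = _add_errors(r2, config.error_rate, rng)
            rid = f"var{var_i}|nt{p}|{orient}|{k}"
            pairs.append(((rid + "/1", r1), (rid + "/2", r2)))
        var_i += 1
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        arr[i] = rng.choice([b for b in _BASES if b != current]).encode()
    return b"".join(arr).decode()


@dataclass
class FeatureTable:
    """Residue-level protein properties with per-feature category tags
    (static / conservation / dynamic)."""

    values: "object"  # pandas DataFrame, rows = aa_pos slots
    categories: dict[str, str]

    def names(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.values.columns)
        return [f for f, c in self.categories.items() if c == category]


def truth_labels(truth: Sequence[GroundTruthSite]) -> np.ndarray:
    """Binary permissibility ground truth: 1 where the domain-averaged
    trafficking probability exceeds 0.5."""
    return np.array([1 if np.mean(list(s.p_se.values())) > 0.5 else 0
                     for s in truth])


def simulate_features(truth: Sequence[GroundTruthSite],
                      effect_size: float = 1.0, n_static: int = 5,
                      n_conservation: int = 21, n_dynamic: int = 20,
                      seed: int = 0) -> FeatureTable:
    """Protein-property table in three categories.

    Static and conservation features are unit Gaussian noise independent of
    site class. Dynamic features carry a class-dependent mean shift of
    ``effect_size * 2 * (p_mean - 0.5)`` standard deviations, where ``p_mean``
    is the site's domain-averaged trafficking probability — flexibility tracks
    permissibility continuously, so only dynamic features are informative.
    """
    import pandas as pd

    if min(n_static, n_conservation, n_dynamic) < 1:
        raise ValueError("each category needs at least one feature")
    rng = np.random.default_rng(seed)
    n = len(truth)
    p_mean = np.array([np.mean(list(s.p_se.values())) for s in truth])
    shift = effect_size * 2.0 * (p_mean - 0.5)
    cols, cats = {}, {}
    for i in range(n_static):
        name = f"static_{i + 1}"
        cols[name] = rng.standard_normal(n)
        cats[name] = "static"
    for i in range(n_conservation):
        name = f"cons_{i + 1}"
        cols[name] = rng.standard_normal(n)
        cats[name] = "conservation"
    for i in range(n_dynamic):
        name = f"mode_{i + 1}"
        cols[name] = shift + rng.standard_normal(n)
        cats[name] = "dynamic"
    index = pd.Index([s.aa_pos for s in truth], name="aa_pos")
    return FeatureTable(pd.DataFrame(cols, index=index), cats)


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------

# log-normal parameters of the two DiBAC populations (arbitrary units):
# hyperpolarized cells exclude the anionic dye (low signal)
_DYE_HYPER = (np.log(120.0), 0.45)
_DYE_DEPOL = (np.log(1200.0), 0.45)
_K_HALF_MM = 15.0  # external K+ at which depolarization halves the weight


def _k_attenuation(k_ext: float) -> float:
    """Fraction of functional-channel cells still hyperpolarized at the given
    external K+ (mM); decreasing in k_ext (raising K+ depolarizes)."""
    return 1.0 / (1.0 + k_ext / _K_HALF_MM)


def simulate_flow(activity: float, k_ext: float = 2.0,
                  light_shift: float = 0.0, bleach_rate: float = 0.0,
                  n_events: int = 10_000, seed: int = 0):
    """DiBAC-style flow events for one sample.

    The dye channel is a two-component log-normal mixture whose
    hyperpolarized-component weight is ``activity * (1 + light_shift) *
    g(k_ext)`` (clipped to [0, 1]); all raw intensities decay by
    ``exp(-bleach_rate * t_acq)`` over the acquisition. Scatter and marker
    channels are fixed log-normals. Returns a pandas DataFrame (one row per
    event, ``t_acq`` strictly increasing).
    """
    import pandas as pd

    if not 0.0 <= activity <= 1.0:
        raise ValueError("activity must be in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    w = float(np.clip(activity * (1.0 + light_shift) * _k_attenuation(k_ext),
                      0.0, 1.0))
    hyper = rng.random(n_events) < w
    mu = np.where(hyper, _DYE_HYPER[0], _DYE_DEPOL[0])
    sd = np.where(hyper, _DYE_HYPER[1], _DYE_DEPOL[1])
    dye = np.exp(rng.normal(mu, sd))
    fsc_a = np.exp(rng.normal(np.log(5e4), 0.30, n_events))
    fsc_h = fsc_a * np.exp(rng.normal(0.0, 0.05, n_events))
    fsc_w = np.exp(rng.normal(np.log(70.0), 0.10, n_events))
    ssc_a = np.exp(rng.normal(np.log(3e4), 0.40, n_events))
    marker = np.exp(rng.normal(np.log(1e3), 0.60, n_events))
    t_acq = np.arange(n_events)
    decay = np.exp(-bleach_rate * t_acq)
    df = pd.DataFrame({
        "fsc_a": fsc_a * decay, "fsc_h": fsc_h * decay,
        "fsc_w": fsc_w * decay, "ssc_a": ssc_a * decay,
        "marker": marker * decay, "dye": dye * decay,
        "t_acq": t_acq,
    })
    return df


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_fastq_pairs(pairs, r1_path: str | Path, r2_path: str | Path) -> None:
    """Standard 4-line FASTQ, Phred+33, quality 'I' for every base."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for (id1, s1), (id2, s2) in pairs:
            f1.write(f"@{id1}\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{id2}\n{s2}\n+\n{'I' * len(s2)}\n")


def write_truth_tsv(truth: Sequence[GroundTruthSite], path: str | Path) -> None:
    domains = sorted(truth[0].p_se) if truth else []
    with open(path, "w") as fh:
        fh.write("aa_pos\tsite_class\t" +
                 "\t".join(f"p_se_{d}" for d in domains) + "\n")
        for s in truth:
            fh.write(f"{s.aa_pos}\t{s.site_class}\t" +
                     "\t".join(f"{s.p_se[d]:.4g}" for d in domains) + "\n")


def write_flow_tsv(events, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)
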