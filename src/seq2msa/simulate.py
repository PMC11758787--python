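"""Simulation of true alignments under a rich indel + substitution model.

Each record is produced by (i) sampling a random rooted binary tree whose
branch lengths sum to a total drawn uniformly from a configured range,
(ii) drawing a root sequence from the stationary frequencies of the
substitution model, and (iii) evolving it along every branch under

* insertions and deletions as a Gillespie process: events arrive at rate
  (RI + RD) * L per unit branch length (L the current sequence length,
  rates relative to the substitution rate), each event an insertion with
  probability RI / (RI + RD); event lengths follow truncated Zipf laws
  with independent exponents AI and AD for the two event types;
* substitutions per surviving site over its residence time on the branch,
  via the transition matrix of a GTR or WAG rate matrix scaled by the
  site's discrete-gamma rate category.

Because every alignment column is tracked from its birth event, the leaf
rows of the returned alignment are mutually consistent by construction:
the true MSA is the event history, not an inference.

The insertion/deletion rate and length-exponent ranges of the default
configuration describe indel evolution across the tree of life as
estimated by ABC on empirical alignments; the default GTR frequencies and
exchangeabilities characterize yeast intron sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from .represent import encode_input, encode_output
from .types import ALPHABETS, DatasetRecord, Msa, PhyloTree, SequenceSet
from .wag import WAG_FREQS, WAG_ORDER, wag_exchange_matrix

log = logging.getLogger(__name__)

#: GTR stationary frequencies in base order T, C, A, G (yeast introns)
DEFAULT_GTR_FREQS = (0.37, 0.166, 0.307, 0.158)
#: exchangeability parameters a..e (pairs TC, TA, TG, CA, CG; AG fixed to 1)
DEFAULT_GTR_RATES = (0.444, 0.0843, 0.116, 0.107, 0.00027)


class ZeroLengthSequence(RuntimeError):
    """The evolving sequence was deleted down to length zero."""


@dataclass
class IndelModel:
    """Insertion/deletion dynamics relative to the substitution rate.

    RI/RD are event rates per site, AI/AD the Zipf exponents of the
    insertion/deletion length distributions P(k) ∝ k^-a truncated at
    ``max_indel_len``.
    """

    RI: float = 0.01
    RD: float = 0.01
    AI: float = 1.5
    AD: float = 1.5
    max_indel_len: int = 50

    def __post_init__(self) -> None:
        if self.RI < 0 or self.RD < 0:
            raise ValueError("indel rates must be nonnegative")
        if self.AI <= 1 or self.AD <= 1:
            raise ValueError("Zipf exponents must exceed 1")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be at least 1")


def sample_zipf_length(a: float, max_len: int, rng: np.random.Generator) -> int:
    """Draw k in [1, max_len] with probability proportional to k^-a."""
    if a <= 1:
        raise ValueError("Zipf exponent must exceed 1")
    if max_len < 1:
        raise ValueError("max_len must be at least 1")
    pmf = np.arange(1, max_len + 1, dtype=float) ** (-a)
    pmf /= pmf.sum()
    return int(rng.choice(max_len, p=pmf)) + 1


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rate of each of K equal-probability categories of a mean-1 gamma."""
    if shape <= 0 or n_categories < 1:
        raise ValueError("shape must be positive and n_categories >= 1")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    bounds = gammaincinv(shape, np.arange(1, k) / k) / shape
    upper = np.concatenate([gammainc(shape + 1, shape * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(shape + 1, shape * bounds)])
    return k * (upper - lower)


@dataclass
class SubstitutionModel:
    """GTR+G (DNA, base order T,C,A,G) or WAG+G (protein) with discrete gamma.

    For GTR the five exchangeabilities are the Yang REV parameters a..e for
    the pairs TC, TA, TG, CA, CG; the sixth (AG) is fixed to 1.  The rate
    matrix is normalized to one expected substitution per site per unit time.
    """

    kind: str = "GTR+G"
    freqs: tuple = DEFAULT_GTR_FREQS
    rates: tuple = DEFAULT_GTR_RATES
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("GTR+G", "WAG+G"):
            raise ValueError(f"unknown substitution model {self.kind!r}")
        if self.kind == "WAG+G":
            self.freqs = tuple(WAG_FREQS)
        f = np.asarray(self.freqs, float)
        # published frequency vectors are often rounded (e.g. summing to 1.001);
        # renormalize within a small tolerance, reject anything worse
        if abs(f.sum() - 1) > 5e-3:
            raise ValueError(f"frequencies sum to {f.sum()}, not 1")
        self.freqs = tuple(f / f.sum())
        if any(r < 0 for r in np.atleast_1d(self.rates)):
            raise ValueError("exchangeability rates must be nonnegative")
        self._build()

    @property
    def alphabet(self) -> str:
        return "DNA" if self.kind == "GTR+G" else "protein"

    @property
    def letters(self) -> str:
        return ALPHABETS["DNA"] if self.kind == "GTR+G" else WAG_ORDER

    def _build(self) -> None:
        pi = np.asarray(self.freqs, float)
        n = len(pi)
        s = np.zeros((n, n))
        if self.kind == "GTR+G":
            a, b, c, d, e = self.rates
            # base order T C A G; pairs (TC)=a (TA)=b (TG)=c (CA)=d (CG)=e (AG)=1
            pairs = {(0, 1): a, (0, 2): b, (0, 3): c, (1, 2): d, (1, 3): e, (2, 3): 1.0}
            for (i, j), r in pairs.items():
                s[i, j] = s[j, i] = r
        else:
            s = wag_exchange_matrix()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        q /= -(pi * np.diag(q)).sum()  # one expected substitution / site / unit time
        self.Q = q
        # reversible model: symmetrize and eigendecompose once for fast expm
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2)
        self._eigw = w
        self._left = v / sqrt_pi[:, None]      # D^{-1/2} V
        self._right = (v * sqrt_pi[:, None]).T  # V^T D^{1/2}
        self.category_rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1."""
        p = (self._left * np.exp(self._eigw * t)) @ self._right
        return np.clip(p, 0.0, None)


def sample_tree(n_leaves: int, tree_length_range: tuple[float, float], rng: np.random.Generator) -> PhyloTree:
    """Random rooted binary topology with branch lengths summing to a drawn total.

    The topology is grown by uniform random joins of subtree roots; branch
    lengths are i.i.d. exponentials rescaled so their sum equals the total
    tree length drawn uniformly from ``tree_length_range``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    lo, hi = tree_length_range
    if lo > hi:
        raise ValueError("tree length range inverted")
    total = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    # linked construction: nodes as (label, [children])
    roots: list[dict] = [{"label": f"seq{i + 1}", "children": []} for i in range(n_leaves)]
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        b = roots.pop(j)
        a = roots.pop(i)
        roots.append({"label": None, "children": [a, b]})
    parent: list[int] = []
    length: list[float] = []
    labels: list[str | None] = []

    def emit(node: dict, parent_idx: int) -> None:
        idx = len(parent)
        parent.append(parent_idx)
        length.append(0.0)
        labels.append(node["label"])
        for ch in node["children"]:
            emit(ch, idx)

    emit(roots[0], -1)
    n_edges = len(parent) - 1
    raw = rng.exponential(1.0, size=n_edges)
    raw *= total / raw.sum()
    for k, i in enumerate(range(1, len(parent))):
        length[i] = float(raw[k])
    return PhyloTree(parent, length, labels)


def _evolve_branch(site_ids: list[int], chars: np.ndarray, t: float,
                   subst: SubstitutionModel, indel: IndelModel,
                   categories: dict[int, int], master: list[int],
                   next_site_id: list[int], rng: np.random.Generator,
                   pi: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Evolve one branch; returns the child's (site ids, characters).

    ``categories`` maps site id -> gamma category (extended for insertions);
    ``master`` is the global alignment-column order (mutated in place);
    ``next_site_id`` is a one-element counter box.
    """
    ids = list(site_ids)
    ch = list(chars)
    birth: dict[int, float] = {}
    total_rate = indel.RI + indel.RD
    if total_rate > 0:
        tau = 0.0
        while True:
            L = len(ids)
            if L == 0:
                raise ZeroLengthSequence
            tau += rng.exponential(1.0 / (total_rate * L))
            if tau > t:
                break
            if rng.random() < indel.RI / total_rate:
                ln = sample_zipf_length(indel.AI, indel.max_indel_len, rng)
                pos = int(rng.integers(0, L + 1))  # L+1 inter-site slots
                new_ids = list(range(next_site_id[0], next_site_id[0] + ln))
                next_site_id[0] += ln
                if pos > 0:
                    anchor = master.index(ids[pos - 1]) + 1
                else:
                    anchor = master.index(ids[0])
                master[anchor:anchor] = new_ids
                ids[pos:pos] = new_ids
                new_chars = rng.choice(len(pi), size=ln, p=pi)
                ch[pos:pos] = list(new_chars)
                for sid in new_ids:
                    categories[sid] = int(rng.integers(0, subst.n_categories))
                    birth[sid] = tau
            else:
                ln = sample_zipf_length(indel.AD, indel.max_indel_len, rng)
                start = int(rng.integers(0, L))  # overhang truncated at the end
                del ids[start:start + ln]
                del ch[start:start + ln]
        if len(ids) == 0:
            raise ZeroLengthSequence
    # substitutions: full-residence sites vectorized per category,
    # mid-branch insertions handled individually over (t - birth)
    ch_arr = np.array(ch, dtype=np.intp)
    cats = np.array([categories[s] for s in ids], dtype=np.intp)
    res_full = np.array([s not in birth for s in ids])
    if t > 0:
        u = rng.random(len(ids))
        out = ch_arr.copy()
        for cat in range(subst.n_categories):
            mask = res_full & (cats == cat)
            if mask.any():
                p = subst.transition_matrix(t * subst.category_rates[cat])
                cum = np.cumsum(p, axis=1)
                cum[:, -1] = 1.0
                rows = cum[ch_arr[mask]]
                out[mask] = (rows < u[mask, None]).sum(axis=1)
        for k, sid in enumerate(ids):
            if sid in birth:
                dt = (t - birth[sid]) * subst.category_rates[categories[sid]]
                p = subst.transition_matrix(dt)
                cum = np.cumsum(p[ch_arr[k]])
                cum[-1] = 1.0
                out[k] = int(np.searchsorted(cum, u[k], side="right"))
        ch_arr = out
    return ids, ch_arr


def evolve(tree: PhyloTree, root_length: int, subst: SubstitutionModel,
           indel: IndelModel, rng: np.random.Generator) -> tuple[Msa, SequenceSet]:
    """Simulate sequences down a tree; returns (true alignment, unaligned leaves).

    Raises ZeroLengthSequence when a lineage is deleted away entirely;
    callers re-simulate the record.
    """
    if root_length < 1:
        raise ValueError("root_length must be at least 1")
    pi = np.asarray(subst.freqs, float)
    root_ids = list(range(root_length))
    master = list(root_ids)
    next_site_id = [root_length]
    categories = {s: int(rng.integers(0, subst.n_categories)) for s in root_ids}
    root_chars = rng.choice(len(pi), size=root_length, p=pi)

    node_state: dict[int, tuple[list[int], np.ndarray]] = {}
    root_idx = tree.parent.index(-1)
    node_state[root_idx] = (root_ids, root_chars)
    for i in range(len(tree.parent)):  # children follow parents in index order
        p = tree.parent[i]
        if p < 0:
            continue
        ids, chars = node_state[p]
        node_state[i] = _evolve_branch(ids, np.asarray(chars), tree.length[i], subst,
                                       indel, categories, master, next_site_id, rng, pi)

    letters = subst.letters
    leaf_idx = [i for i, lb in enumerate(tree.labels) if lb is not None]
    if all(tree.labels[i].startswith("seq") and tree.labels[i][3:].isdigit() for i in leaf_idx):
        leaf_idx.sort(key=lambda i: int(tree.labels[i][3:]))  # seq1, seq2, ... order
    # otherwise keep the tree's own (preorder) leaf order
    leaf_maps = []
    for i in leaf_idx:
        ids, chars = node_state[i]
        leaf_maps.append(dict(zip(ids, (letters[c] for c in chars))))
    live_columns = [sid for sid in master if any(sid in m for m in leaf_maps)]
    rows = ["".join(m.get(sid, "-") for sid in live_columns) for m in leaf_maps]
    ids = [tree.labels[i] for i in leaf_idx]
    msa = Msa(ids, rows, subst.alphabet)
    return msa, msa.ungapped()


@dataclass
class SimulationConfig:
    """Study conditions for one dataset of simulated alignments.

    Defaults reproduce the nucleotide reference conditions: 10 sequences,
    total tree length U(0.05, 0.1), root length uniform on [32, 44],
    RI, RD ~ U(0, 0.05), AI, AD ~ U(1.01, 2.0), GTR+G with yeast-intron
    frequencies and exchangeabilities.
    """

    n_sequences: int = 10
    n_records: int = 100
    tree_length_range: tuple[float, float] = (0.05, 0.1)
    root_length_range: tuple[int, int] = (32, 44)
    RI_range: tuple[float, float] = (0.0, 0.05)
    RD_range: tuple[float, float] = (0.0, 0.05)
    AI_range: tuple[float, float] = (1.01, 2.0)
    AD_range: tuple[float, float] = (1.01, 2.0)
    substitution: SubstitutionModel = field(default_factory=SubstitutionModel)
    max_indel_len: int = 50
    input_scheme: str = "concat"
    output_scheme: str = "spaces"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be at least 2")
        for name in ("tree_length_range", "root_length_range", "RI_range", "RD_range", "AI_range", "AD_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} inverted: {lo} > {hi}")

    def subspace_of(self, outer: "SimulationConfig") -> bool:
        """True when every parameter range is contained in ``outer``'s."""
        return violating_range(self, outer) is None


def violating_range(inner: SimulationConfig, outer: SimulationConfig) -> str | None:
    """Name of the first inner range not contained in the outer one, else None."""
    for name in ("tree_length_range", "root_length_range", "RI_range", "RD_range", "AI_range", "AD_range"):
        (ilo, ihi), (olo, ohi) = getattr(inner, name), getattr(outer, name)
        if ilo < olo or ihi > ohi:
            return name
    return None


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def simulate_record(config: SimulationConfig, rng: np.random.Generator) -> DatasetRecord:
    """One (unaligned sequences, true alignment) pair with freshly drawn parameters."""
    while True:
        tree = sample_tree(config.n_sequences, config.tree_length_range, rng)
        root_length = int(rng.integers(config.root_length_range[0], config.root_length_range[1] + 1))
        indel = IndelModel(
            RI=_uniform(rng, *config.RI_range), RD=_uniform(rng, *config.RD_range),
            AI=max(_uniform(rng, *config.AI_range), 1.0 + 1e-9),
            AD=max(_uniform(rng, *config.AD_range), 1.0 + 1e-9),
            max_indel_len=config.max_indel_len,
        )
        try:
            truth, seqset = evolve(tree, root_length, config.substitution, indel, rng)
        except ZeroLengthSequence:
            log.info("sequence deleted to length 0; re-simulating record")
            continue
        params = {
            "RI": indel.RI, "RD": indel.RD, "AI": indel.AI, "AD": indel.AD,
            "root_length": root_length, "tree_length": tree.total_length,
            "newick": tree.to_newick(),
        }
        source = encode_input(seqset, config.input_scheme)
        target = encode_output(truth, config.output_scheme)
        return DatasetRecord(source=source, target=target, truth=truth, params=params)


def simulate_dataset(config: SimulationConfig, n_records: int | None = None,
                     rng: np.random.Generator | None = None) -> list[DatasetRecord]:
    """Independent records under the configured parameter ranges; reproducible from seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_records if n_records is None else n_records
    return [simulate_record(config, rng) for _ in range(n)]


def pairwise_config(**overrides) -> SimulationConfig:
    """Convenience preset for pairwise (k=2) DNA simulation at short root lengths."""
    base = dict(n_sequences=2, root_length_range=(10, 20),
                RI_range=(0.0, 0.02), RD_range=(0.0, 0.02))
    base.update(overrides)
    return SimulationConfig(**base)
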