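"""Protein-level comparisons and codon-level selection analysis.

The selection machinery fits a GY94-style codon model in which every branch
class of a labeled phylogeny gets its own dN/dS ratio (omega), with a single
transition/transversion ratio (kappa) and F3x4 codon frequencies estimated
from the alignment; nested fits are compared with a likelihood ratio test
against the chi-square distribution.  Because omega is undefined when a
branch carries no synonymous substitutions, per-branch expected
nonsynonymous (N) and synonymous (S) substitution counts are always reported
alongside omega, and estimates that hit the cap are flagged.

Ancestral substitution mapping uses unit-cost parsimony; a change on a
branch is "unequivocal" when the parent and child states are identical in
every most-parsimonious reconstruction.
"""
from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import edlib
import numpy as np
from scipy import optimize, stats

from .codon import (
    CODON_INDEX,
    CodonPropagator,
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    _is_transition,
    f3x4,
    nonsyn_rate_fraction,
    translate,
)
from .core import LabeledTree, TreeNode

OMEGA_CAP = 999.0


# ---------------------------------------------------------------------------
# Codon alignment container


@dataclass
class CodonAlignment:
    """Aligned coding sequences; gaps (if any) in codon units."""

    names: list
    rows: list
    pseudogene_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pseudogene_flags:
            self.pseudogene_flags = [False] * len(self.names)
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")
        for name, row, pseudo in zip(self.names, self.rows, self.pseudogene_flags):
            if pseudo:
                continue
            for k in range(0, len(row) - 3, 3):
                codon = row[k : k + 3].upper()
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {name} at nt {k}")

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def drop_pseudogenes(self) -> "CodonAlignment":
        keep = [i for i, p in enumerate(self.pseudogene_flags) if not p]
        return CodonAlignment(
            names=[self.names[i] for i in keep],
            rows=[self.rows[i] for i in keep],
        )


# ---------------------------------------------------------------------------
# Translation, pseudogene diagnostics, frame forcing


class TranslatedProtein(NamedTuple):
    sequence: str
    numbering: tuple  # per residue: -signal_len..-1 then 1..n_mature


def translate_cds(
    cds: str, signal_peptide_len: int = 26, pseudogene: bool = False
) -> TranslatedProtein:
    """Conceptual translation with signal-peptide numbering.

    Residues are numbered -signal_peptide_len..-1 for the signal peptide and
    1.. for the mature protein; the trailing stop is removed.  An internal
    stop raises unless ``pseudogene`` mode, which emits '*'.
    """
    protein = translate(cds)
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein and not pseudogene:
        raise ValueError(f"internal stop codon at residue {protein.index('*') + 1}")
    numbering = tuple(
        i - signal_peptide_len if i < signal_peptide_len else i - signal_peptide_len + 1
        for i in range(len(protein))
    )
    return TranslatedProtein(sequence=protein, numbering=numbering)


@dataclass
class PseudogeneDiagnostics:
    frameshifts: list     # (position in query CDS, indel length, "ins"/"del")
    premature_stops: list  # nt positions (codon starts) of stops before the reference stop

    @property
    def is_pseudogene(self) -> bool:
        return bool(self.frameshifts or self.premature_stops)


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def detect_pseudogene(
    cds: str, reference_cds: str, min_identity: float = 0.60
) -> PseudogeneDiagnostics:
    """Diagnose inactivating mutations against a translatable homolog.

    The pair is aligned globally with affine gap costs (substitutions are
    never rendered as indel pairs, unlike unit-cost alignment).  Indels whose
    length is not a multiple of 3 are frameshifts; stop codons upstream of
    the reference stop (in the frame restored after each frameshift) are
    premature stops.  Positions are 0-based in the query.  Random nucleotide
    pairs align at ~48% identity by chance, so the alignability cutoff sits
    above that.
    """
    from skbio.alignment import pair_align_nucl

    res = pair_align_nucl(cds, reference_cds, mode="global", free_ends=False)
    a1, a2 = res.paths[0].to_aligned((cds, reference_cds))
    matches = sum(x == y for x, y in zip(a1, a2) if x != "-" and y != "-")
    identity = matches / len(a1)
    if identity < min_identity:
        raise ValueError(f"sequences too divergent to align ({identity:.0%} identity)")
    frameshifts = []
    repaired = []  # query sequence with frame restored (placeholders for dels)
    qpos = 0
    # skbio cigar: M consumes both; D consumes query only; I reference only
    for n, op in _CIG_RE.findall(res.paths[0].to_cigar()):
        n = int(n)
        if op == "M":
            repaired.append(cds[qpos : qpos + n])
            qpos += n
        elif op == "D":  # extra bases in query
            if n % 3:
                frameshifts.append((qpos, n, "ins"))
            else:
                repaired.append(cds[qpos : qpos + n])
            qpos += n
        else:  # "I": bases missing from query
            if n % 3:
                frameshifts.append((qpos, n, "del"))
                repaired.append("N" * n)
            # in-frame deletion: no placeholder needed, frame is preserved
    seq = "".join(repaired)
    stops = []
    for k in range(0, len(seq) - 3, 3):  # exclude the terminal stop position
        codon = seq[k : k + 3]
        if codon in STOP_CODONS:
            stops.append(k)
    return PseudogeneDiagnostics(frameshifts=frameshifts, premature_stops=stops)


def force_frame(cds: str, insertion_sites: Sequence[int]) -> str:
    """Repair a pseudogene reading frame for display: insert one placeholder
    base per site, translate with 'X' at placeholder codons and '*' at stops.
    """
    sites = list(insertion_sites)
    if sites != sorted(sites):
        raise ValueError("insertion sites must be in ascending order")
    seq = cds
    for offset, site in enumerate(sites):
        pos = site + offset
        if pos > len(seq):
            raise ValueError(f"insertion site {site} outside sequence")
        seq = seq[:pos] + "N" + seq[pos:]
    out = []
    for k in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[k : k + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(GENETIC_CODE.get(codon, "X"))
    protein = "".join(out)
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


# ---------------------------------------------------------------------------
# Protein alignment statistics


def variable_sites(
    alignment: dict, group_members: Sequence[str]
) -> tuple[int, list]:
    """Number of columns at which the group members are not all identical.

    Gap-containing columns count only if the non-gap states differ (pairwise
    deletion).  Returns (count, 0-based column list).
    """
    if len(group_members) < 2:
        raise ValueError("group must contain at least 2 sequences")
    rows = [alignment[m] for m in group_members]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned rows must have equal length")
    columns = []
    for i, col in enumerate(zip(*rows)):
        states = {c for c in col if c not in "-."}
        if len(states) > 1:
            columns.append(i)
    return len(columns), columns


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical positions over aligned, ungapped columns."""
    if len(seq_a) == len(seq_b):
        pairs = list(zip(seq_a, seq_b))
    else:
        res = edlib.align(seq_a, seq_b, mode="NW", task="path")
        pairs = []
        qpos = tpos = 0
        for n, op in _CIG_RE.findall(res["cigar"]):
            n = int(n)
            if op in "=XM":
                pairs.extend(zip(seq_a[qpos : qpos + n], seq_b[tpos : tpos + n]))
                qpos += n
                tpos += n
            elif op == "I":
                qpos += n
            else:
                tpos += n
    compared = [(a, b) for a, b in pairs if a not in "-." and b not in "-."]
    if not compared:
        raise ValueError("no comparable (ungapped) columns")
    matches = sum(a == b for a, b in compared)
    return 100.0 * matches / len(compared)


# ---------------------------------------------------------------------------
# Nei-Gojobori (NG86) counting


class NeiGojoboriResult(NamedTuple):
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    dn: float
    ds: float

    @property
    def ratio(self) -> float:
        if self.ds <= 0:
            return math.inf if self.dn > 0 else math.nan
        return self.dn / self.ds


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon; mutations to
    stop codons are excluded from the opportunity."""
    n = s = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        syn = valid = 0
        for nt in "TCAG":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
            n += 1.0 - syn / valid
    return n, s


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average (nonsyn, syn) differences over all orderings of the mutational
    pathway between two codons, skipping pathways through stops."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    n_tot = s_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = ca
        n = s = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            n_tot += n
            s_tot += s
            n_paths += 1
    if n_paths == 0:  # all pathways pass through stops: count direct changes
        return float(len(positions)), 0.0
    return n_tot / n_paths, s_tot / n_paths


def nei_gojobori(cds_a: str, cds_b: str) -> NeiGojoboriResult:
    """Unweighted NG86 synonymous/nonsynonymous counting with Jukes-Cantor
    correction.  Requires equal-length, gap-free, stop-free sequences."""
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("length not divisible by 3")
    N = S = Nd = Sd = 0.0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k : k + 3].upper(), cds_b[k : k + 3].upper()
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon at nt {k}")
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = _pathway_diffs(ca, cb)
        Nd += nd
        Sd += sd

    def jc(p: float) -> float:
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * p / 3)

    return NeiGojoboriResult(
        n_sites=N, s_sites=S, n_diffs=Nd, s_diffs=Sd,
        dn=jc(Nd / N if N else 0.0), ds=jc(Sd / S if S else 0.0),
    )


# ---------------------------------------------------------------------------
# Branch-model maximum likelihood


@dataclass
class BranchEdge:
    leaves: frozenset
    cls: int
    t: float
    expected_nonsyn: float
    expected_syn: float


@dataclass
class BranchModelFit:
    lnl: float
    kappa: float
    omega_by_class: dict
    edges: list                   # BranchEdge per branch
    pi: np.ndarray
    n_codons: int
    n_params: int
    capped_classes: list = field(default_factory=list)
    unidentifiable: bool = False

    def omega(self, cls: int = 0) -> float:
        return self.omega_by_class[cls]

    def edge(self, leaf_names: Sequence[str]) -> BranchEdge:
        want = frozenset(leaf_names)
        for e in self.edges:
            if e.leaves == want:
                return e
        raise KeyError(f"no fitted branch subtends {sorted(want)}")


def _prepare_patterns(aln: CodonAlignment, tree: LabeledTree):
    """Complete deletion of gapped/ambiguous codon columns; pattern
    compression."""
    leaves = tree.leaf_names()
    missing = set(leaves) - set(aln.names)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    rows = {n: aln.row(n) for n in leaves}
    n_cod = aln.n_codons()
    cols = []
    for k in range(n_cod):
        codons = [rows[n][3 * k : 3 * k + 3].upper() for n in leaves]
        if all(c in CODON_INDEX for c in codons):
            cols.append([CODON_INDEX[c] for c in codons])
    if not cols:
        raise ValueError("no ungapped codon columns")
    mat = np.array(cols).T  # taxa x columns
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return leaves, patterns, counts.astype(float), len(cols)


def _log_likelihood(tree, leaf_index, patterns, counts, pi, props, lengths):
    npat = patterns.shape[1]
    logscale = np.zeros(npat)
    partial = {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        L = np.ones((N_SENSE, npat))
        for child in node.children:
            P = props[child.cls].transition_matrix(lengths[id(child)])
            if child.is_leaf:
                contrib = P[:, patterns[leaf_index[child.name]]]
            else:
                contrib = P @ partial[id(child)]
            L *= contrib
        mx = L.max(axis=0)
        mx[mx == 0] = 1.0
        L /= mx
        logscale += np.log(mx)
        partial[id(node)] = L
    root = partial[id(tree.root)]
    site_like = pi @ root
    return float((counts * (np.log(site_like) + logscale)).sum())


def fit_branch_model(
    aln: CodonAlignment,
    tree: LabeledTree,
    n_starts: int = 3,
    omega_cap: float = OMEGA_CAP,
) -> BranchModelFit:
    """ML fit of branch lengths, kappa, and one omega per branch class.

    Multi-start L-BFGS-B in log-parameter space guards against local optima
    (and enforces the nesting inequality lnL(alt) >= lnL(null) in practice).
    Omegas at the cap are flagged; a tree whose total fitted length is ~0
    (identical sequences) is flagged unidentifiable.
    """
    aln = aln.drop_pseudogenes()
    leaves, patterns, counts, n_cod = _prepare_patterns(aln, tree)
    leaf_index = {n: i for i, n in enumerate(leaves)}
    pi = f3x4([aln.row(n) for n in leaves])
    edges = tree.edges()
    classes = sorted(tree.branch_classes())
    n_edges = len(edges)

    def unpack(x):
        ts = np.exp(x[:n_edges])
        kappa = math.exp(x[n_edges])
        omegas = {c: math.exp(v) for c, v in zip(classes, x[n_edges + 1 :])}
        return ts, kappa, omegas

    def negloglik(x):
        ts, kappa, omegas = unpack(x)
        props = {c: CodonPropagator(kappa, omegas[c], pi) for c in classes}
        lengths = {id(e): t for e, t in zip(edges, ts)}
        return -_log_likelihood(tree, leaf_index, patterns, counts, pi, props, lengths)

    t0 = np.array([max(e.length, 0.02) for e in edges])
    starts = []
    omega_inits = [0.3, 1.0, 3.0, 0.1, 10.0]
    for i in range(n_starts):
        w0 = omega_inits[i % len(omega_inits)]
        starts.append(
            np.concatenate(
                [np.log(t0 * (1.0 if i == 0 else 0.5 * 2**i)),
                 [math.log(2.0)],
                 np.full(len(classes), math.log(w0))]
            )
        )
    bounds = (
        [(math.log(1e-7), math.log(20.0))] * n_edges
        + [(math.log(0.05), math.log(50.0))]
        + [(math.log(1e-6), math.log(omega_cap))] * len(classes)
    )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    ts, kappa, omegas = unpack(best.x)
    capped = [c for c, w in omegas.items() if w >= omega_cap * 0.99]
    unident = float(ts.sum()) < 1e-5

    fitted_edges = []
    for e, t in zip(edges, ts):
        rho_n = nonsyn_rate_fraction(kappa, omegas[e.cls], pi)
        total = t * n_cod
        fitted_edges.append(
            BranchEdge(
                leaves=tree.leafset_under(e),
                cls=e.cls,
                t=float(t),
                expected_nonsyn=total * rho_n,
                expected_syn=total * (1 - rho_n),
            )
        )
    return BranchModelFit(
        lnl=-float(best.fun),
        kappa=kappa,
        omega_by_class=omegas,
        edges=fitted_edges,
        pi=pi,
        n_codons=n_cod,
        n_params=n_edges + 1 + len(classes),
        capped_classes=capped,
        unidentifiable=unident,
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(null_fit: BranchModelFit, alt_fit: BranchModelFit, df: Optional[int] = None) -> LRTResult:
    """Likelihood ratio test of nested branch models: 2(lnL_alt - lnL_null)
    against chi-square with df = difference in free omega parameters."""
    n_null = len(null_fit.omega_by_class)
    n_alt = len(alt_fit.omega_by_class)
    if n_alt <= n_null:
        raise ValueError("alternative model must have more omega classes than the null")
    if df is None:
        df = n_alt - n_null
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                f"negative LRT statistic {stat:.3g} (optimizer noise); floored at 0"
            )
        stat = 0.0
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Parsimony substitution mapping


@dataclass
class SubstitutionEvent:
    branch: frozenset   # leaf set under the branch
    column: int         # 0-based alignment column
    parent_state: str
    child_state: str
    unequivocal: bool


_INF = 10**9


def _sankoff_up(tree: LabeledTree, column: dict, states: list) -> dict:
    """up[node][s] = min changes in the subtree of node given node has state
    s.  Leaves with missing data ('-', 'X') accept any state at cost 0."""
    ns = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    up = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = column.get(node.name, "-")
            if obs in sidx:
                vec = np.full(ns, _INF)
                vec[sidx[obs]] = 0
            else:
                vec = np.zeros(ns, dtype=np.int64)
        else:
            vec = np.zeros(ns, dtype=np.int64)
            for child in node.children:
                cvec = up[id(child)]
                # min over child state t of up[t] + [s != t]
                best = cvec.min()
                vec = vec + np.minimum(cvec, best + 1)
        up[id(node)] = vec
    return up


def _sankoff_down(tree: LabeledTree, up: dict, ns: int) -> dict:
    """down[node][s] = min changes outside the subtree of node given node has
    state s."""
    down = {id(tree.root): np.zeros(ns, dtype=np.int64)}
    for node in tree.preorder():
        if node.is_leaf and node.parent is None:
            continue
        for child in node.children:
            sib_sum = np.zeros(ns, dtype=np.int64)
            for sib in node.children:
                if sib is child:
                    continue
                svec = up[id(sib)]
                sib_sum = sib_sum + np.minimum(svec, svec.min() + 1)
            base = down[id(node)] + sib_sum  # cost given node state s'
            best = base.min()
            down[id(child)] = np.minimum(base, best + 1)
    return down


def parsimony_score(tree: LabeledTree, column: dict) -> int:
    """Minimum number of changes for one alignment column (unit costs)."""
    states = sorted({v for v in column.values() if v not in "-X."})
    if len(states) <= 1:
        return 0
    up = _sankoff_up(tree, column, states)
    return int(up[id(tree.root)].min())


def reconstruct_changes(
    protein_alignment: dict,
    tree: LabeledTree,
    target_branch: Sequence[str],
) -> list[SubstitutionEvent]:
    """Substitution events on the branch subtending ``target_branch`` leaves.

    For each column, the set of (parent state, child state) pairs achievable
    in some most-parsimonious reconstruction is computed exactly; an event is
    unequivocal when every such pair is the same ordered pair with parent !=
    child.  Events present in some but not all reconstructions are listed
    with ``unequivocal=False``.
    """
    child_node = tree.find_edge(target_branch)
    parent_node = child_node.parent
    lengths = {len(r) for r in protein_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    ncol = lengths.pop()
    missing = set(tree.leaf_names()) - set(protein_alignment)
    if missing:
        raise ValueError(f"alignment missing taxa: {sorted(missing)}")

    events = []
    for col in range(ncol):
        column = {name: protein_alignment[name][col] for name in tree.leaf_names()}
        states = sorted({v for v in column.values() if v not in "-X."})
        if len(states) <= 1:
            continue
        ns = len(states)
        up = _sankoff_up(tree, column, states)
        down = _sankoff_down(tree, up, ns)
        total_min = int(up[id(tree.root)].min())

        # A two-child root splits what is really one unrooted branch; collapse
        # it so the "parent" is the node on the far side of that branch.
        collapse_root = (
            parent_node is tree.root and len(parent_node.children) == 2
        )
        if collapse_root:
            sib = next(c for c in parent_node.children if c is not child_node)
            parent_cost = lambda x_i: int(up[id(sib)][x_i])
        else:
            sib_cost = {}
            for x_i in range(ns):
                c = 0
                for sib in parent_node.children:
                    if sib is child_node:
                        continue
                    svec = up[id(sib)]
                    c += int(min(svec[x_i], svec.min() + 1))
                sib_cost[x_i] = c
            parent_cost = lambda x_i: (
                int(down[id(parent_node)][x_i]) + sib_cost[x_i]
            )
        feasible = []
        for x_i in range(ns):
            for y_i in range(ns):
                cost = parent_cost(x_i) + (x_i != y_i) + int(up[id(child_node)][y_i])
                if cost == total_min:
                    feasible.append((x_i, y_i))
        changing = [(x, y) for x, y in feasible if x != y]
        if not changing:
            continue
        unequiv = len(feasible) == 1
        for x, y in sorted(set(changing)):
            events.append(
                SubstitutionEvent(
                    branch=tree.leafset_under(child_node),
                    column=col,
                    parent_state=states[x],
                    child_state=states[y],
                    unequivocal=unequiv,
                )
            )
    return events


def protein_alignment_from_codons(aln: CodonAlignment) -> dict:
    """Translate every (non-pseudogene) row; gap codons become '-'."""
    out = {}
    for name, row, pseudo in zip(aln.names, aln.rows, aln.pseudogene_flags):
        if pseudo:
            continue
        prot = []
        for k in range(0, len(row), 3):
            codon = row[k : k + 3].upper()
            if "-" in codon or "." in codon:
                prot.append("-")
            else:
                prot.append(GENETIC_CODE.get(codon, "X"))
        out[name] = "".join(prot)
    if out and all(s[-1] in "*-" for s in out.values()):
        out = {k: v[:-1] for k, v in out.items()}  # drop the stop column
    return out
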