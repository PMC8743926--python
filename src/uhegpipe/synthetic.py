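"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the analysis inputs so every downstream stage is
testable without external downloads:

* :func:`simulate_expression` — normalized log2 expression matrices over
  several experiments and postnatal time points, with a planted set of
  constitutively high-expressed probes, 1-3 redundant probes per gene, a
  fraction of non-protein-coding and unmapped probes, and i.i.d. Gaussian
  noise on the log2 scale (RMA output is approximately Gaussian there).
* :func:`simulate_ontology` — a single-rooted is_a DAG shaped like the
  Mammalian Phenotype Ontology: a configurable number of top-level terms
  (29 by default: 27 abnormal-phenotype groups plus the "normal phenotype"
  and "no phenotypic analysis" subtrees that the analysis excises),
  optional multi-parent terms, and one obsolete stanza.
* :func:`simulate_allele_report` — allele-level mutational-study records
  with a heavy-tailed (geometric) terms-per-gene distribution, distinct
  study identifiers, allowed and excluded zygosity classes, and decoy
  records that must be removed by the zygosity filter.

Every generator also returns a :class:`TruthManifest` holding the planted
truth (probe->gene map, term levels, per-gene expected post-propagation
term sets, expected tri-state status), computed by simple independent
walks over the generator's own structures rather than through the pipeline
modules.  Identical spec + seed reproduces every output bit-identically.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix, SampleMeta, write_expression_matrix, write_sample_sheet
from .ontology import Ontology, Term, write_obo

__all__ = [
    "ExpressionSimSpec",
    "OntologySimSpec",
    "AnnotationSimSpec",
    "TruthManifest",
    "simulate_expression",
    "simulate_ontology",
    "simulate_allele_report",
    "simulate_bundle",
]

# fixed per-component seed offsets derived from the master seed
SEED_EXPRESSION = 11
SEED_ONTOLOGY = 23
SEED_ANNOTATION = 37
SEED_QC = 53
SEED_HOUSEKEEPING = 71

PROTEIN_CODING = "protein coding gene"
NONCODING_FEATURES = ("lncRNA gene", "miRNA gene", "pseudogene")
EXCLUDED_ZYGOSITY_TOKENS = ("cn", "cx", "ot")


class SimSpecError(ValueError):
    """A simulation spec violates one of its invariants."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

# experiments mirror the study layout: 5 postnatal time points across 3
# experiments (2-4 biological replicates each), 15 samples in total, with
# the day-1 samples exempt from the intersection requirement
DEFAULT_EXPERIMENTS = (
    ("E-SYN-A", 21, 2),
    ("E-SYN-B", 10, 4),
    ("E-SYN-C", 1, 3),
    ("E-SYN-C", 15, 3),
    ("E-SYN-C", 30, 3),
)


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Planted-high expression simulation parameters (log2 units)."""

    seed: int = 0
    experiments: tuple[tuple[str, int, int], ...] = DEFAULT_EXPERIMENTS
    n_probes: int = 2000
    n_high: int = 100
    mu_high: float = 12.0
    mu_background: float = 8.0
    sigma: float = 1.0
    optional_days: frozenset[int] = frozenset({1})
    optional_samples: frozenset[str] = frozenset()
    probes_per_gene_max: int = 3
    frac_noncoding: float = 0.08
    frac_unmapped: float = 0.02

    def validate(self) -> None:
        if self.n_high > self.n_probes:
            raise SimSpecError(f"n_high ({self.n_high}) exceeds n_probes ({self.n_probes})")
        if self.sigma < 0:
            raise SimSpecError(f"sigma must be >= 0, got {self.sigma}")
        if not self.experiments:
            raise SimSpecError("experiments list is empty")
        for exp_id, day, reps in self.experiments:
            if reps < 2:
                raise SimSpecError(
                    f"n_replicates must be >= 2 (got {reps} for {exp_id} day {day})"
                )
            if day < 0:
                raise SimSpecError(f"postnatal_day must be >= 0, got {day}")
        if self.probes_per_gene_max < 1:
            raise SimSpecError("probes_per_gene_max must be >= 1")
        for name in ("frac_noncoding", "frac_unmapped"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimSpecError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class OntologySimSpec:
    """MPO-like DAG shape parameters."""

    seed: int = 0
    n_top_level: int = 29
    max_depth: int = 6
    branching: float = 2.0
    multiparent_prob: float = 0.15

    def validate(self) -> None:
        if self.max_depth < 4:
            raise SimSpecError(
                f"max_depth must be >= 4 to exercise level truncation, got {self.max_depth}"
            )
        if self.n_top_level < 3:
            raise SimSpecError("n_top_level must be >= 3 (two slots are excluded subtrees)")
        if not 0 <= self.multiparent_prob <= 1:
            raise SimSpecError(f"multiparent_prob must lie in [0, 1], got {self.multiparent_prob}")
        if self.branching <= 0:
            raise SimSpecError("branching must be positive")


@dataclass(frozen=True)
class AnnotationSimSpec:
    """Allele-report simulation parameters.

    ``terms_per_gene_dispersion`` is the mean of the geometric
    terms-per-gene distribution (heavy tail: most genes get few terms, a
    few get many).  The unannotated / normal-only fractions default to the
    study's observed tri-state proportions (~36% of genes without any
    mutant record, ~12% with records but no abnormal term).
    """

    seed: int = 0
    genes: tuple[tuple[str, str], ...] = ()  # (mgi_id, gene_symbol)
    terms_per_gene_dispersion: float = 3.0
    max_studies_per_gene: int = 5
    frac_unannotated: float = 0.36
    frac_normal_only: float = 0.12
    decoy_record_prob: float = 0.2
    allowed_tokens: tuple[str, ...] = ("hm", "ht")

    def validate(self) -> None:
        if not self.genes:
            raise SimSpecError("gene list is empty")
        for name in ("frac_unannotated", "frac_normal_only", "decoy_record_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimSpecError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_unannotated + self.frac_normal_only > 1:
            raise SimSpecError("frac_unannotated + frac_normal_only exceeds 1")
        if self.terms_per_gene_dispersion < 1:
            raise SimSpecError("terms_per_gene_dispersion must be >= 1")
        if self.max_studies_per_gene < 1:
            raise SimSpecError("max_studies_per_gene must be >= 1")


@dataclass
class TruthManifest:
    """Planted truth for every generated entity."""

    planted_high_probes: set[str] = field(default_factory=set)
    probe_to_gene: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    # probe -> (gene_symbol, mgi_id, feature_type); unmapped probes absent
    planted_genes: dict[str, str] = field(default_factory=dict)  # mgi -> symbol
    coding_genes: dict[str, str] = field(default_factory=dict)
    term_levels: dict[str, int] = field(default_factory=dict)
    excluded_closure: set[str] = field(default_factory=set)
    root_id: str = ""
    gene_direct_terms: dict[str, set[str]] = field(default_factory=dict)
    gene_truth_sets: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    gene_status: dict[str, str] = field(default_factory=dict)
    gene_study_counts: dict[str, int] = field(default_factory=dict)
    hk_symbols: list[str] = field(default_factory=list)
    hk_expected: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        for name in (
            "planted_high_probes",
            "probe_to_gene",
            "planted_genes",
            "coding_genes",
            "term_levels",
            "excluded_closure",
            "gene_direct_terms",
            "gene_truth_sets",
            "gene_status",
            "gene_study_counts",
            "hk_expected",
        ):
            mine, theirs = getattr(self, name), getattr(other, name)
            if isinstance(mine, dict):
                mine.update(theirs)
            else:
                mine |= theirs
        if other.root_id:
            self.root_id = other.root_id
        if other.hk_symbols:
            self.hk_symbols = list(other.hk_symbols)
        return self


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------


def _build_probe_universe(spec: ExpressionSimSpec, rng: np.random.Generator):
    """Assign probes to genes: planted-high first, then coding background,
    non-coding, and unmapped probes."""
    n_noncoding = int(round(spec.frac_noncoding * spec.n_probes))
    n_unmapped = int(round(spec.frac_unmapped * spec.n_probes))
    n_bg = spec.n_probes - spec.n_high - n_noncoding - n_unmapped
    if n_bg < 0:
        raise SimSpecError("n_probes too small for n_high plus noncoding/unmapped fractions")

    probe_ids = [f"{100000 + i}_at" for i in range(spec.n_probes)]
    probe_map: dict[str, tuple[str, str, str]] = {}
    planted_probes: list[str] = []
    planted_genes: dict[str, str] = {}
    coding_genes: dict[str, str] = {}

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = probe_ids[cursor : cursor + n]
        cursor += n
        return out

    gi = 0
    remaining = spec.n_high
    while remaining > 0:
        nper = int(min(rng.integers(1, spec.probes_per_gene_max + 1), remaining))
        mgi, sym = f"MGI:1{gi:06d}", f"Hi{gi:04d}"
        for p in take(nper):
            probe_map[p] = (sym, mgi, PROTEIN_CODING)
            planted_probes.append(p)
        planted_genes[mgi] = sym
        coding_genes[mgi] = sym
        remaining -= nper
        gi += 1

    gi = 0
    remaining = n_bg
    while remaining > 0:
        nper = int(min(rng.integers(1, spec.probes_per_gene_max + 1), remaining))
        mgi, sym = f"MGI:2{gi:06d}", f"Bg{gi:04d}"
        for p in take(nper):
            probe_map[p] = (sym, mgi, PROTEIN_CODING)
        coding_genes[mgi] = sym
        remaining -= nper
        gi += 1

    for i, p in enumerate(take(n_noncoding)):
        ft = NONCODING_FEATURES[i % len(NONCODING_FEATURES)]
        probe_map[p] = (f"Nc{i:04d}", f"MGI:3{i:06d}", ft)
    take(n_unmapped)  # deliberately absent from the map
    return probe_map, planted_probes, planted_genes, coding_genes


def _sample_sheet(spec: ExpressionSimSpec) -> list[SampleMeta]:
    samples = []
    for exp_id, day, reps in spec.experiments:
        for r in range(1, reps + 1):
            sid = f"{exp_id}_PD{day}_r{r}"
            required = day not in spec.optional_days and sid not in spec.optional_samples
            samples.append(SampleMeta(sid, exp_id, day, r, required))
    return samples


def simulate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, TruthManifest]:
    """Simulate a planted-high log2 expression matrix across experiments."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + SEED_EXPRESSION)
    probe_map, planted_probes, planted_genes, coding_genes = _build_probe_universe(spec, rng)
    samples = _sample_sheet(spec)

    probe_ids = [f"{100000 + i}_at" for i in range(spec.n_probes)]
    means = np.full(spec.n_probes, spec.mu_background)
    planted_idx = {p: i for i, p in enumerate(probe_ids)}
    for p in planted_probes:
        means[planted_idx[p]] = spec.mu_high
    values = np.tile(means[:, None], (1, len(samples)))
    if spec.sigma > 0:
        values = values + rng.normal(0.0, spec.sigma, size=values.shape)
    df = pd.DataFrame(values, index=probe_ids, columns=[s.sample_id for s in samples])
    matrix = ExpressionMatrix(df, samples)

    truth = TruthManifest(
        planted_high_probes=set(planted_probes),
        probe_to_gene=probe_map,
        planted_genes=planted_genes,
        coding_genes=coding_genes,
    )
    return matrix, truth


# --------------------------------------------------------------------------
# ontology
# --------------------------------------------------------------------------

ROOT_ID = "MP:0000001"
NORMAL_NAME = "normal phenotype"
NO_ANALYSIS_NAME = "no phenotypic analysis"


def _bfs_levels(children: Mapping[str, list[str]], root: str) -> dict[str, int]:
    """Min-depth levels by plain breadth-first search (truth oracle)."""
    levels = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for t in frontier:
            for c in children.get(t, []):
                if c not in levels:
                    levels[c] = levels[t] + 1
                    nxt.append(c)
        frontier = nxt
    return levels


def simulate_ontology(spec: OntologySimSpec) -> tuple[str, TruthManifest]:
    """Generate an MPO-like OBO document plus its level/exclusion truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + SEED_ONTOLOGY)

    counter = [1]

    def new_id() -> str:
        counter[0] += 1
        return f"MP:{counter[0]:07d}"

    names: dict[str, str] = {ROOT_ID: "mammalian phenotype"}
    parents: dict[str, set[str]] = {ROOT_ID: set()}

    def add(name: str, *parent_ids: str) -> str:
        tid = new_id()
        names[tid] = name
        parents[tid] = set(parent_ids)
        return tid

    n_abnormal_top = spec.n_top_level - 2
    abnormal_top = [
        add(f"abnormal phenotype group {i + 1:02d}", ROOT_ID) for i in range(n_abnormal_top)
    ]
    normal_id = add(NORMAL_NAME, ROOT_ID)
    no_analysis_id = add(NO_ANALYSIS_NAME, ROOT_ID)
    # small closed subtree under "normal phenotype" to exercise child exclusion
    normal_children = [add("normal phenotype variant a", normal_id),
                       add("normal phenotype variant b", normal_id)]
    add("normal phenotype variant a1", normal_children[0])

    # grow abnormal levels 2..max_depth; the first top term carries a forced
    # chain so level-4 truncation is always exercised
    abnormal_by_gen: dict[int, list[str]] = {1: abnormal_top}
    chain_carrier = abnormal_top[0]
    for gen in range(2, spec.max_depth + 1):
        new_terms: list[str] = []
        shallower = [t for g in range(1, gen) for t in abnormal_by_gen[g]]
        for parent in abnormal_by_gen[gen - 1]:
            k = int(rng.poisson(spec.branching))
            if parent == chain_carrier:
                k = max(k, 1)
            for _ in range(k):
                tid = add(f"abnormal phenotype term {counter[0] + 1}", parent)
                if spec.multiparent_prob > 0 and rng.random() < spec.multiparent_prob:
                    candidates = [c for c in shallower if c != parent]
                    if candidates:
                        extra = candidates[int(rng.integers(len(candidates)))]
                        parents[tid].add(extra)
                new_terms.append(tid)
            if parent == chain_carrier:
                chain_carrier = new_terms[-1] if new_terms else parent
        abnormal_by_gen[gen] = new_terms

    obsolete_id = add("obsolete retired term")
    parents[obsolete_id] = set()

    terms = {
        tid: Term(tid, names[tid], frozenset(parents[tid]), obsolete=(tid == obsolete_id))
        for tid in names
    }
    ontology = Ontology(terms)
    text = write_obo(ontology)

    children: dict[str, list[str]] = {}
    for tid, ps in parents.items():
        if tid == obsolete_id:
            continue
        for p in ps:
            children.setdefault(p, []).append(tid)
    levels = _bfs_levels(children, ROOT_ID)

    def down(seed_id: str) -> set[str]:
        out, stack = {seed_id}, [seed_id]
        while stack:
            for c in children.get(stack.pop(), []):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    truth = TruthManifest(
        term_levels=levels,
        excluded_closure=down(normal_id) | down(no_analysis_id),
        root_id=ROOT_ID,
    )
    return text, truth


# --------------------------------------------------------------------------
# allele report
# --------------------------------------------------------------------------


def _truth_ancestors(terms: Mapping[str, Term], tid: str) -> set[str]:
    out: set[str] = set()
    stack = list(terms[tid].parent_ids)
    while stack:
        p = stack.pop()
        if p not in out:
            out.add(p)
            stack.extend(terms[p].parent_ids)
    return out


def simulate_allele_report(
    spec: AnnotationSimSpec, ontology: Ontology, ontology_truth: TruthManifest
) -> tuple[pd.DataFrame, TruthManifest]:
    """Generate an allele-level phenotype report and its per-gene truth.

    Truth sets (expected post-propagation, post-truncation annotation) are
    computed by walking the generator's own parent map, independently of
    the pipeline's graph machinery.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + SEED_ANNOTATION)
    genes = [(g, g) if isinstance(g, str) else tuple(g) for g in spec.genes]

    levels = ontology_truth.term_levels
    excluded = ontology_truth.excluded_closure
    root = ontology_truth.root_id
    abnormal_pool = sorted(
        t for t, lv in levels.items() if lv >= 1 and t not in excluded
    )
    normal_pool = sorted(t for t in excluded if levels.get(t, 0) >= 1)
    max_level = 4  # truth sets follow the pipeline's default truncation

    n = len(genes)
    order = rng.permutation(n)
    n_un = int(round(spec.frac_unannotated * n))
    n_norm = int(round(spec.frac_normal_only * n))
    unannotated = {genes[i][0] for i in order[:n_un]}
    normal_only = {genes[i][0] for i in order[n_un : n_un + n_norm]}

    rows = []
    truth = TruthManifest()
    allele_counter = [0]
    study_counter = [0]

    def allele_id() -> str:
        allele_counter[0] += 1
        return f"MGI:9{allele_counter[0]:06d}"

    def study_id() -> str:
        study_counter[0] += 1
        return f"PMID:{7000000 + study_counter[0]}"

    for mgi, sym in genes:
        if mgi in unannotated:
            truth.gene_status[mgi] = "no_mutant"
            truth.gene_direct_terms[mgi] = set()
            truth.gene_truth_sets[mgi] = set()
            truth.gene_study_counts[mgi] = 0
            continue

        if mgi in normal_only:
            k = int(rng.integers(1, 3))
            chosen = list(rng.choice(normal_pool, size=min(k, len(normal_pool)), replace=False))
            sid = study_id()
            rows.append(
                (allele_id(), mgi, sym,
                 str(rng.choice(spec.allowed_tokens)), sid, ",".join(sorted(chosen)))
            )
            truth.gene_status[mgi] = "mutant_no_abnormal"
            truth.gene_direct_terms[mgi] = set(chosen)
            truth.gene_truth_sets[mgi] = set()
            truth.gene_study_counts[mgi] = 1
            continue

        # abnormal gene: heavy-tailed number of direct terms
        k = int(min(rng.geometric(1.0 / spec.terms_per_gene_dispersion), len(abnormal_pool)))
        chosen = sorted(rng.choice(abnormal_pool, size=k, replace=False))
        n_studies = int(min(rng.geometric(0.6), spec.max_studies_per_gene))
        studies = [study_id() for _ in range(n_studies)]
        # distribute direct terms across one record per study
        assignment: dict[int, list[str]] = {i: [] for i in range(n_studies)}
        for t in chosen:
            assignment[int(rng.integers(n_studies))].append(t)
        for i, sid in enumerate(studies):
            # occasional record with no study identifier, terms still count
            use_sid = "" if rng.random() < 0.05 else sid
            rows.append(
                (allele_id(), mgi, sym,
                 str(rng.choice(spec.allowed_tokens)), use_sid,
                 ",".join(sorted(assignment[i])))
            )
        if rng.random() < spec.decoy_record_prob:
            # record from a disallowed genotype class; its terms must be
            # invisible to a correctly filtering pipeline
            decoys = list(rng.choice(abnormal_pool, size=2, replace=False))
            rows.append(
                (allele_id(), mgi, sym,
                 str(rng.choice(EXCLUDED_ZYGOSITY_TOKENS)), study_id(),
                 ",".join(sorted(decoys)))
            )

        propagated: set[tuple[str, int]] = set()
        for t in chosen:
            for a in {t} | _truth_ancestors(ontology.terms, t):
                if a == root or a in excluded:
                    continue
                if 1 <= levels[a] <= max_level:
                    propagated.add((a, levels[a]))
        truth.gene_status[mgi] = "abnormal" if propagated else "mutant_no_abnormal"
        truth.gene_direct_terms[mgi] = set(chosen)
        truth.gene_truth_sets[mgi] = propagated
        # distinct nonempty study ids among this gene's allowed-zygosity records
        written = {r[4] for r in rows if r[1] == mgi and r[3] in spec.allowed_tokens and r[4]}
        truth.gene_study_counts[mgi] = len(written)

    report = pd.DataFrame(
        rows,
        columns=["allele_id", "mgi_id", "gene_symbol", "zygosity_category", "study_id", "term_ids"],
    ).sort_values(["mgi_id", "allele_id"], kind="stable").reset_index(drop=True)
    return report, truth


# --------------------------------------------------------------------------
# bundle: all six input files + truth + ready-to-run config
# --------------------------------------------------------------------------


def _simulate_qc(samples: Sequence[SampleMeta], bad_samples: Sequence[SampleMeta], seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed + SEED_QC)
    rows = []
    for s in samples:
        rows.append(
            (s.sample_id,
             round(float(rng.uniform(40, 85)), 2),
             round(float(rng.uniform(-2.5, 2.5)), 3),
             round(float(rng.uniform(-0.9, 0.9)), 3))
        )
    for s in bad_samples:
        # degraded arrays: both 3'/5' ratios out of range, as in the
        # excluded experiment of the reference analysis
        sign = 1 if rng.random() < 0.5 else -1
        rows.append(
            (s.sample_id,
             round(float(rng.uniform(40, 85)), 2),
             round(sign * float(rng.uniform(3.5, 5.0)), 3),
             round(sign * float(rng.uniform(1.2, 2.0)), 3))
        )
    return pd.DataFrame(rows, columns=["sample_id", "background", "actin_ratio", "gapdh_ratio"])


def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    expression_spec: ExpressionSimSpec | None = None,
    ontology_spec: OntologySimSpec | None = None,
    annotation_spec: AnnotationSimSpec | None = None,
    k: int = 150,
    include_failing_experiment: bool = True,
) -> tuple[dict[str, Path], TruthManifest]:
    """Write a complete synthetic input bundle plus truth manifest.

    Produces the same file dialects the pipeline reads (per-experiment
    expression TSVs, sample sheet, QC metrics, probe map, OBO ontology,
    allele report, housekeeping list), a ready-to-run ``config.yaml``, and
    a ``truth/`` directory.  ``k`` is the top-K written into the config,
    scaled to the synthetic probe universe.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    espec = expression_spec or ExpressionSimSpec(seed=seed)
    ospec = ontology_spec or OntologySimSpec(seed=seed)

    matrix, truth = simulate_expression(espec)
    obo_text, otruth = simulate_ontology(ospec)
    truth.merge(otruth)
    from .ontology import parse_obo

    ontology = parse_obo(obo_text)

    aspec = annotation_spec or AnnotationSimSpec(
        seed=seed, genes=tuple(sorted(truth.coding_genes.items()))
    )
    if annotation_spec is not None and not annotation_spec.genes:
        aspec = replace(annotation_spec, genes=tuple(sorted(truth.coding_genes.items())))
    report, atruth = simulate_allele_report(aspec, ontology, otruth)
    truth.merge(atruth)

    # housekeeping list: a quarter of the planted genes, an equal slice of
    # background genes, plus symbols absent from the array
    rng = np.random.default_rng(seed + SEED_HOUSEKEEPING)
    planted_syms = sorted(truth.planted_genes.values())
    bg_syms = sorted(set(truth.coding_genes.values()) - set(planted_syms))
    n_hk_planted = max(1, len(planted_syms) // 4)
    hk = sorted(
        list(rng.choice(planted_syms, size=n_hk_planted, replace=False))
        + list(rng.choice(bg_syms, size=min(len(bg_syms), 2 * n_hk_planted), replace=False))
        + [f"Off{i:03d}" for i in range(3)]
    )
    truth.hk_symbols = hk
    planted_in_hk = {m for m, s in truth.planted_genes.items() if s in set(hk)}
    truth.hk_expected = {
        "n_in_hk": len(planted_in_hk),
        "n_in_hk_abnormal": sum(
            1 for m in planted_in_hk if truth.gene_status.get(m) == "abnormal"
        ),
    }

    # write per-experiment matrices
    paths: dict[str, Path] = {}
    exp_ids = []
    for exp_id in dict.fromkeys(e[0] for e in espec.experiments):
        cols = [s.sample_id for s in matrix.samples if s.experiment_id == exp_id]
        sub = matrix.subset_samples(cols)
        p = outdir / f"expression_{exp_id}.tsv"
        write_expression_matrix(sub, p)
        exp_ids.append(exp_id)
        paths[f"expression_{exp_id}"] = p

    samples = list(matrix.samples)
    bad_samples: list[SampleMeta] = []
    if include_failing_experiment:
        bad_samples = [SampleMeta(f"E-SYN-BAD_PD7_r{i}", "E-SYN-BAD", 7, i) for i in (1, 2, 3)]
        rngb = np.random.default_rng(seed + SEED_QC + 1)
        bad_vals = espec.mu_background + (
            rngb.normal(0, max(espec.sigma, 1e-9), size=(espec.n_probes, 3))
            if espec.sigma >= 0 else 0.0
        )
        bad_df = pd.DataFrame(
            bad_vals, index=matrix.probe_ids, columns=[s.sample_id for s in bad_samples]
        )
        bad_matrix = ExpressionMatrix(bad_df, bad_samples)
        p = outdir / "expression_E-SYN-BAD.tsv"
        write_expression_matrix(bad_matrix, p)
        exp_ids.append("E-SYN-BAD")
        paths["expression_E-SYN-BAD"] = p

    paths["sample_sheet"] = outdir / "samples.tsv"
    write_sample_sheet(samples + bad_samples, paths["sample_sheet"])

    paths["qc_metrics"] = outdir / "qc_metrics.tsv"
    _simulate_qc(samples, bad_samples, seed).to_csv(paths["qc_metrics"], sep="\t", index=False)

    paths["probe_map"] = outdir / "probe_map.tsv"
    pd.DataFrame(
        [(p, g[0], g[1], g[2]) for p, g in sorted(truth.probe_to_gene.items())],
        columns=["probe_id", "gene_symbol", "mgi_id", "feature_type"],
    ).to_csv(paths["probe_map"], sep="\t", index=False)

    paths["ontology"] = outdir / "ontology.obo"
    paths["ontology"].write_text(obo_text)

    paths["allele_report"] = outdir / "alleles.tsv"
    report.to_csv(paths["allele_report"], sep="\t", index=False)

    paths["housekeeping"] = outdir / "housekeeping.txt"
    paths["housekeeping"].write_text("\n".join(hk) + "\n")

    config = {
        "expression_matrices": [f"expression_{e}.tsv" for e in exp_ids],
        "sample_sheet": "samples.tsv",
        "qc_metrics": "qc_metrics.tsv",
        "probe_map": "probe_map.tsv",
        "ontology": "ontology.obo",
        "allele_report": "alleles.tsv",
        "housekeeping": "housekeeping.txt",
        "k": k,
        "output_dir": "results",
        "seed": seed,
    }
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))

    _write_truth(outdir / "truth", truth, seed)
    return paths, truth


def _write_truth(tdir: Path, truth: TruthManifest, seed: int) -> None:
    tdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(truth.planted_high_probes), columns=["probe_id"]).to_csv(
        tdir / "planted_probes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(m, s) for m, s in sorted(truth.planted_genes.items())],
        columns=["mgi_id", "gene_symbol"],
    ).to_csv(tdir / "planted_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, lv) for t, lv in sorted(truth.term_levels.items())],
        columns=["term_id", "level"],
    ).to_csv(tdir / "term_levels.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (g, truth.gene_status[g], truth.gene_study_counts.get(g, 0),
             ",".join(sorted(truth.gene_direct_terms.get(g, set()))),
             ",".join(f"{t}@{lv}" for t, lv in sorted(truth.gene_truth_sets.get(g, set()))))
            for g in sorted(truth.gene_status)
        ],
        columns=["mgi_id", "status", "n_studies", "direct_terms", "truth_set"],
    ).to_csv(tdir / "gene_truth.tsv", sep="\t", index=False)
    (tdir / "run_metadata.txt").write_text(
        textwrap.dedent(
            f"""\
            generator: uhegpipe.synthetic
            master_seed: {seed}
            seed_offsets: expression={SEED_EXPRESSION} ontology={SEED_ONTOLOGY} annotation={SEED_ANNOTATION} qc={SEED_QC} housekeeping={SEED_HOUSEKEEPING}
            """
        )
    )
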