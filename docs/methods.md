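# Methods

`clonoscope` analyses haploid multilocus marker data from partially clonal
fungal populations. Its target system is a heterothallic, seed-transmitted
grass endophyte typed at microsatellite (SSR) loci and at presence/absence
markers for the secondary-metabolite gene clusters that determine alkaloid
production. This note records the statistical models, the decision rules,
the defaults and their rationale, and what the synthetic data generator
does and does not emulate.

## Multilocus genotypes, clone correction, rarefaction

Because the organism is haploid and largely clonal, identical multilocus
genotypes (MLGs) are treated as members of one clone. `assign_mlg`
partitions isolates by exact identity of the full allele vector; a missing
allele is a distinct token, so two isolates group together only when every
scored locus matches *and* their missing patterns coincide. This strict
rule can split a true clone with a dropped locus into two MLGs, but it can
never merge distinct clones — the conservative direction for statistics
whose null is "everything is one clone".

`clone_correct` keeps the first occurrence of each MLG within each unit of
the chosen level (population, region, or total); a seedable random
representative is available but the deterministic first-occurrence rule is
the default so that repeated runs agree exactly.

Expected genotype richness at a common sample size (eMLG) uses
hypergeometric rarefaction:

    eMLG(n) = Σ_g [ 1 − C(N − N_g, n) / C(N, n) ]

with the classical rarefaction variance (including the pairwise covariance
term) for the standard error. The default depth is the smallest group size
that is at least 10; groups below the depth report their observed MLG
count. Binomial coefficients are evaluated through the hypergeometric pmf,
so large samples do not overflow.

## Index of association

Linkage among loci is the population-genetic signature of clonal
reproduction. For every isolate pair the per-locus distance is 0/1
mismatch; with D the per-pair sum, V_O = var(D) and V_E = Σ_l var(d_l):

    I_A = V_O / V_E − 1
    r̄d  = (V_O − V_E) / (2 Σ_{j<k} √(var_j var_k))

Both are ratios of (co)variances, so the population-vs-sample denominator
convention cancels; a test asserts this by computing both. The statistics
are computed on clone-corrected data by default (level configurable;
`None` analyses all isolates), and groups with fewer than `min_mlg = 5`
genotypes are flagged not-tested rather than reported.

The permutation null shuffles alleles among isolates independently per
locus. This preserves each locus's allele frequencies, hence V_E and the
r̄d denominator, so ranking permutations by r̄d, I_A or V_O gives the same
p-value, computed as (#{perm ≥ obs} + 1)/(B + 1) with B = 999 by default.
With B permutations the p-value lives on the lattice k/(B+1); calibration
tests allow for that lattice width.

## Distances, minimum spanning networks, ordination

Two pairwise distances are provided. The *allele mismatch count* (loci
differing, with pairwise deletion of missing loci and optional rescaling to
the panel size) is the working "haploid genetic distance"; its square feeds
the AMOVA. The *stepwise-mutation distance* per locus is 1 − 2^(−|Δ|) on
repeat counts, averaged over shared loci — appropriate for microsatellites
where single-step mutations are common. Fragment sizes convert to repeat
counts via each locus's motif length and flanking offset; residues beyond
0.25 repeat units warn and round. Being haploid, no genome-addition/loss
model is needed. A pair sharing zero scored loci is an error, not a guess.

Minimum spanning networks are built over MLG representatives with Kruskal's
algorithm. Within each equal-weight block the components are frozen so that
every edge joining the same two components at that weight is recorded:
under the default `all_ties` policy all such edges are added and flagged
`co_minimal` (the selected one also carries `in_tree`), yielding the
reticulated networks used to display clonal complexes; `first` keeps a
strict tree. The `in_tree` edges always total the exhaustive minimum
spanning weight (asserted against a brute-force oracle, and against the
scipy MST weight).

PCoA is classical (Gower) scaling: double-centre −D²/2, eigendecompose,
scale eigenvectors by √λ for λ > 0. Mismatch distances need not be
Euclidean, so negative eigenvalues can occur; they are reported but
excluded from percent-explained, which is normalised over positive
eigenvalues and sums to 100%.

## Diversity indices

Per locus and group: effective allele number Ne = 1/Σp², gene diversity
h = 1 − Σp², and the small-sample unbiased form uh = n/(n−1)·h (undefined
at n = 1, reported as NaN). A locus is polymorphic when ≥ 2 alleles are
observed — no frequency threshold, appropriate for haploid SSR panels.
Private alleles are counted against the other groups of the same grouping;
both the per-locus mean and the group total are emitted because published
tables are ambiguous between the two. Group summaries are means over loci,
and both all-isolate and clone-corrected variants are produced.

## AMOVA and Φ statistics

The hierarchical analysis of molecular variance uses the distance form of
the sums of squares — SS of a group is (1/n)Σ_{i<j} d² — for a two-level
(populations/individuals) or three-level (regions/populations/individuals)
design, with the standard unequal-size coefficients (n', n'', n''') for the
expected mean squares. Φ_CT, Φ_SC, Φ_ST (and Φ_PT for two levels) are
intraclass correlations of the components; the identity
(1−Φ_CT)(1−Φ_SC) = (1−Φ_ST) is asserted to 1e−9. Negative components are
reported as computed, never truncated, so percentages of other rows can
exceed 100 — the behaviour of the classical programs.

Permutation schemes follow the level being tested: individuals among
populations (Φ_ST), individuals among populations within regions (Φ_SC),
and whole populations among regions (Φ_CT). Pairwise differentiation runs
a two-level AMOVA per unit pair, permuting individuals between the two
units, and excludes units with fewer than 5 members (logged, not an
error). The same Φ machinery serves both the SSR statistic (reported as
Fst) and the binary marker-profile statistic (Φ_PT); only the naming
differs in outputs.

## Chemotype prediction

Alkaloid production is predicted from the presence/absence of key pathway
genes; each class yields at most one terminal product:

* **Ergot alkaloids** — ERV (ergovaline) when all of dmaW, easC, easA,
  cloA, lpsB are present; CC (chanoclavine) when dmaW and easC are present
  but the cluster is incomplete.
* **Pyrrolopyrazines** — PER (peramine) when perA5′, perAT2 and the
  reductase domain perAR are present; PPZA2 (pyrrolopyrazine-1,4-diones)
  when the reductase domain is missing.
* **Indole-diterpenes** — a ladder PAS → TDI → TDC → LTB. Under the
  default `table_consistent` rules: TDI (terpendole I) needs idtG and
  idtQ; TDC (terpendole C) additionally needs idtP, idtK and a
  *functional* idtF; LTB (lolitrem B) additionally needs idtJ; PAS
  (paspaline) needs idtG and idtP when idtQ is absent. An idtF copy
  carrying the first-exon deletion (an in-frame stop codon) yields a PCR
  band but cannot carry the late pathway: it is a distinct PSEUDOGENE
  state that satisfies no functional requirement.
* **Lolines** — LOL when all four of lolC, lolA, lolO, lolP are present.

An UNTESTED marker never satisfies a positive requirement (conservative
prediction). The label joins the non-empty products as EAS/PPZ/IDT/LOL.

Two rule sets exist because the published description and the published
genotype table disagree in two places: the prose keys paspaline on
idtG + idtQ and requires functional idtF for terpendole I, while the
printed genotype panel calls terpendole I for pseudogene-idtF genotypes
and paspaline for idtG + idtP genotypes lacking idtQ. The default
`table_consistent` set reproduces the printed panel for 37 of its 38
genotypes; the single divergence (gt-14, where the engine additionally
calls chanoclavine from the stated dmaW + easC rule) is pinned in a test.
The prose variant is available as `methods_text`.

Alkaloid multilocus genotypes (aMLGs) group profiles by exact identity of
the full marker-state vector, with PSEUDOGENE and UNTESTED as distinct
states. Mating-type summaries count A, B and not-detected idiomorphs per
group and always recompute the A:B ratio from the counts (undefined, not
infinite, when B is absent).

### The packaged genotype panel

The package ships a transcription of the published 38-genotype alkaloid
panel (198 isolates across the Faroe Islands, Finland and Spain) and
expands it deterministically to isolate level (ids `<gt>-<region>-<k>`).
Two transcription caveats: the printed per-region count columns sum to
61/90/47 while the running text says 60/91/46–47 — the table is kept as
printed; and the printed mating-type tallies are per genotype, not per
region, so for the few multi-region genotypes the expansion assigns A's
first in region order, making regional mating ratios from this fixture
approximate (their genotype-level totals are exact).

## Synthetic data generator

`simulate` is a forward model of the sampling situation: per population,
a few founder genotypes are drawn from allele pools (each founder allele
comes from a region-private pool with probability θ, the regional
divergence, else from a shared pool); isolates are then generated
sequentially. Each new isolate is, with probability c (clonal fraction), a
copy of a random existing local genotype with per-locus stepwise mutation
(rate μ, ±1 repeat, reflecting bounds at 5–60 repeats); otherwise with
probability s a sexual recombinant of two local parents with per-locus
random parent choice; otherwise a seed-borne arrival of an intact founder
lineage. That last event is deliberately an *intact* genotype copy: a
per-locus fresh draw would itself destroy linkage and recombination would
no longer be the force that erodes r̄d. With probability m the source
population is another one (migration). Mating types are A with probability
`mt_skew`; under the heterothallic constraint a recombination event needs
local parents of both idiomorphs and falls back to a clonal copy when none
exist — with `mt_skew = 1` recombination is therefore structurally
impossible and is forced off. Alkaloid profiles and mating type ride along
clonally (optional marker-loss rate, default 0), so isolates of one clonal
lineage share an aMLG. A truth record (founder genotypes, lineage and
parent of every isolate, event types) is a first-class output.

Defaults mirror the study shape: 3 regions × 5 populations × 16 isolates,
14 loci, clonal fraction 0.8, recombination 0.2, divergence 0.8, migration
0.02, mating-type skew 0.9.

What the generator does *not* emulate: overlapping generations and age
structure; population-specific founder sharing within a region (each
population draws its own founders, so among-population variance within
regions is higher than in seed-connected real populations); linkage
between SSR loci and the alkaloid clusters beyond clonal co-inheritance;
null alleles and genotyping error. Passing recovery tests therefore show
that the estimators respond correctly to clonality, recombination and
divergence in this model — not that real data meet the model's
assumptions.

## Numerical and design choices

* Permutation p-values are (k+1)/(B+1), bounded below by 1/(B+1); every
  stochastic routine takes an explicit seed, and the pipeline derives
  per-stage child seeds from the master seed via a seed sequence, so a
  rerun reproduces every p-value exactly.
* Distance matrices validate symmetry and zero diagonal at construction;
  the Bruvo metric is bounded in [0,1] and zero iff repeat vectors agree
  on all shared loci.
* Degenerate inputs return sentinels rather than crashing: Φ on an
  all-identical dataset is NaN, uh at n = 1 is NaN, the A:B ratio without
  B isolates is not-computable.
* Analysis problem sizes in the drivers and tests (e.g. 199–999
  permutations, 10–200 simulation replicates, populations of 8–120) were
  chosen to make the statistical assertions stable at a few per cent
  precision while keeping a full run interactive.

## Known limitations

* The chemotype engine predicts presence of a pathway product, not
  quantity, and relies on upstream scoring of the idtF deletion; it does
  not read sequence.
* The SSR analyses assume one allele per locus; records with multiple
  peaks must be removed first (`filter_multiallelic`), mirroring standard
  QC for haploid fungi.
* AMOVA on mismatch distances treats loci as exchangeable and unweighted;
  no mutational model enters the variance partition (the Bruvo distance is
  available to ordination/MSN but is not the AMOVA default).
* Model-based population clustering is out of scope; externally derived
  cluster labels can be supplied as a grouping instead.
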