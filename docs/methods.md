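# Methods

## The problem

Soybean looper (*Chrysodeixis includens*), a noctuid pest of soybean in
the southeastern United States, shows evidence of two sympatric
populations ("clans") with limited capacity for cross-hybridization.
Two cheap markers expose the structure:

* **sCOIB** — a mitochondrial *COI* fragment with two C/T SNP sites.
  The haplotype class (T1035 vs C1035) is defined by the base at site
  1035 alone; site 1272 only refines the four-way combined class.
  Maternal inheritance: one haplotype per specimen.
* **sTpiI140** — a hypervariable intron of the Z-linked *Tpi* gene with
  a 7-bp deletion allele (`i65del`) segregating against the undeleted
  allele (`i65+`). Lepidopteran sex chromosomes are ZZ (male) / ZW
  (female): only males can be heterozygous; females are hemizygous.

Because sequencing is performed directly on PCR product, a
heterozygous male's two alleles are sequenced simultaneously. The 7-bp
length difference frameshifts one allele against the other from the
deletion breakpoint onward, so the chromatograph shows superimposed
peaks — rendered in a basecalled read as a run of IUPAC ambiguity
codes that, for the study alleles, opens with the diagnostic
`MMTYAGW` pattern. This signature is what makes heterozygotes (and
hence heterozygote deficit) detectable without cloning.

Three population statistics follow:

* **Wright's F_is** = (H_e − H_o)/H_e per collection, with
  H_o = n_het/n, p = (2·n_delhom + n_het)/(2n), H_e = 2p(1−p).
  F_is = 0 at Hardy–Weinberg equilibrium; strongly positive values
  diagnose the Wahlund effect — heterozygote deficit caused by pooling
  subpopulations with different allele frequencies. Monomorphic
  collections (H_e = 0) are reported as undefined ("nd"), never as 0.
* **Mito–nuclear linkage**: under random mating a Z-linked allele must
  be equally frequent in both mitochondrial haplotype classes. The
  i65del frequency is therefore compared between C1035 and T1035
  specimens per state (paired t-test across states) and correlated
  with T1035 frequency across collections (Pearson r, p from the exact
  transform t = r√(k−2)/√(1−r²)).
* **Diversity**: haplotype diversity h = (n/(n−1))(1 − Σp_i²) and
  nucleotide diversity π (mean pairwise proportion of differing sites,
  gap columns excluded pair-wise), with Nei's large-sample variance for
  h and the Nei/Tajima no-recombination variance for π. No named
  formula is attached to the published ±sd values, so ours are our own
  choice of estimator and are not compared against them.

## The simulator

`simulate_collection` draws, per specimen: mother clan ~
Bernoulli(clan_proportion_B); father clan equal to the mother's with
probability 1 − m (m = `hybridization_rate`, the single parameter
standing in for "limited capacity for cross-hybridization"); mito
haplotype from the mother clan's T1035 frequency; Z alleles from the
per-parent clan del-frequencies — males one from each parent, females
one from the father (standard ZW transmission; only copy number is
attested in the source system, parental origin is the package's
modeling choice). Reads are rendered off fixed reference templates;
heterozygote reads are exactly the expected frameshift signature.

This one-parameter mating model reproduces both phenomena of interest
with no further coupling: at m = 0 and equal clan proportions the
pooled males-only F_is equals the Wahlund closed form
(p_A − p_B)²/(4 p̄ q̄); at m = 0.5 the father's clan is independent of
the mother's and F_is = 0. The mito–nuclear association appears purely
because both markers covary with clan membership.

Defaults are the study conditions: p(T1035|A) = 0.17,
p(T1035|B) = 0.41, p(del|A) = 0, p(del|B) = 1,
clan_proportion_B = 0.12 (the del allele was reported at 12% of pooled
collections and is fixed in ClanB), m = 0.1 (no field estimate exists;
a small value consistent with "limited" cross-mating), noise 0.

Not emulated: trace-level (AB1) signal, indel sequencing errors,
multi-generation backcrossing, hybrid fitness, assortative mating
beyond m, within-allele sequence variation in the intron (so simulated
per-clan diversity is degenerate at 0 — the diversity estimators are
validated on explicit sequence sets instead). Passing tests on
synthetic data therefore demonstrate the calling logic and the
statistical machinery, not robustness to real chromatograph noise.

Unknown-sex collections: each specimen still has a latent sex (drawn
50/50), so hemizygotes occur; tabulation scores them with the same
diploid formula as males (a hemizygote counts as a homozygote). This
deliberately overestimates F_is — females cannot be heterozygous — and
the simulation reproduces that upward bias; it mirrors how
unknown-gender larval collections are scored in the field tables.
Known females are excluded from genotype counting entirely.

## Calling: numerical choices

* SNP sites are located by unique flanking 8-mer anchors (k
  configurable). Absent, duplicated, or wrongly spaced anchors give
  *not found*, and the read is uncallable — never guessed. A
  reverse-complemented read is uncallable by construction.
* The packaged COI template is built so that every non-anchor window
  is ≥3 mismatches from every anchor, and rendering noise never hits
  the anchors or SNP sites; single substitutions can neither destroy
  nor counterfeit an anchor, making class accuracy on rendered noisy
  reads exact by design.
* Tpi calls compare the read against the i65+ consensus, the i65del
  consensus, and the heterozygote signature. Homozygote/hemizygote
  acceptance is exact identity ≥ `min_match` (default 0.95; the
  sources give no threshold, 0.95 keeps 2%-noise reads callable with
  margin). Heterozygote acceptance is *compatibility*: at every
  position the observed base set must be contained in the expected
  code's set — tolerant of basecallers that emit the dominant base
  instead of the ambiguity code, and agnostic to the M = T/A vs
  M = A/C discrepancy in the source's legend.
* Precedence: consensus identity is tested first; heterozygous is
  called only when both consensus identities fail and the read is
  signature-compatible across the breakpoint window. The reverse
  order would be wrong — any pure-allele read is trivially compatible
  with the signature (each of its bases belongs to the superimposed
  pair), so compatibility alone cannot outrank an exact consensus
  match. Uncallable is always preferred over a forced call.
* F_is display values are rounded half-up to two decimals (the mean
  0.4051 must display as 0.41); percent tables round to integers.
* Pooling rule: in the grouped allele-frequency table, a unit with
  fewer than ten specimens of *either* haplotype class is merged into
  a single "Pool" unit (strictly < 10; one combined pool, not pairwise
  merges).

## Known limitations

* Heterozygote allele sequences cannot be phased from a superimposed
  read; in clan summaries a heterozygote contributes the reference
  consensus of each allele, flattening clan diversity estimates.
* The π/h standard deviations use classical large-sample estimators;
  no bootstrap is provided.
* The t-test layer assumes the paired design over state units; no
  multiple-testing correction is applied (none is used in the source
  analysis it mirrors).
* Problem sizes in the test suite (collections of 10²–2·10⁴
  specimens) are chosen to make stochastic checks resolve within
  3-standard-error bands in seconds on one CPU.
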