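# Methods

This note documents the models behind `delselect`, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## Encoding architecture

The selection template is `primer5 + barcode + primer3`. Defaults are two
18 nt primer-binding sites around a 12 nt randomized encoding region
(48 nt total), giving 4¹² ≈ 1.68×10⁷ addressable molecules. Only the
primers' length and role are constrained by the experimental design, so the
shipped primer sequences are arbitrary fixed GC-balanced 18-mers, chosen to
contain no EcoRV site and no long self-overlaps (which would create
spurious merge offsets); every entry point accepts other sequences.

The positive-control (spike-in) barcode is `ACCGATATCTGG`: the EcoRV
recognition sequence `GATATC` (the enzyme's standard site, blunt cutter)
centred at offset 3 of the encoding region. The experiment only requires
the site to lie *within* the encoding region; centring is a neutral choice.

Libraries are represented as barcode → (class, frequency) tables. The
background is a uniform sample of distinct non-spike barcodes; the default
background size is 10⁵ distinct members. Full N12 enumeration (16.7M rows)
is supported for short regions via `enumerate_library` but is unnecessary
for the statistics of interest: the spike-in's marginal behaviour under
selection and multinomial sequencing depends only on its own frequency,
not on how the background mass is partitioned (verified by the
pooled-vs-enumerated equivalence test). Whether the real library is a full
random region or a curated subset cannot be distinguished from these data;
both modes exist and the default is the sampled one.

## Selection model

One round of selection is modelled as class-dependent Bernoulli survival:
catalyst members survive (are biotinylated and captured) with probability
`p_cat`, inactive members with `p_bg` (non-specific retention /
background biotinylation). Sequencing of a pool is a multinomial draw at
finite depth. In expectation, a spike at pre-frequency `f0` reaches

    f1 = f0·p_cat / (f0·p_cat + (1−f0)·p_bg)
    E  = f1/f0 = R / (1 + f0·(R−1)),   R = p_cat/p_bg

so enrichment identifies only the survival *ratio* R and is capped by the
dilution ceiling `1/f0`. Absolute capture efficiencies are not reported
by the experiment and remain free parameters; the headline enrichments
pin down R through the closed form (R = 3000 ↔ 1200-fold at 1/2000;
R = 124.75 ↔ 100-fold and R = 81.2326 ↔ 70-fold at 1/500). The simulation
samples the post-selection pool directly from the survival-reweighted
frequencies (the infinite-molecule limit of per-molecule Bernoulli
thinning, appropriate because the physical pool is vastly deeper than the
sequencing depth).

Single-round selection is the tested regime, matching the experiment;
multi-round chaining can be composed manually but is not validated.
PCR amplification bias is not modelled: the experiment provides no bias
data, and injecting unconstrained per-member efficiency noise would add
variance no observation can calibrate.

## Read simulation

Read 1 sequences the template strand 5′→3′, read 2 the reverse
complement. Defaults are 2×75 nt at constant Q30 with substitution errors
i.i.d. per base at rate 0.001; with a 48 nt insert both reads run through
into the opposite adapter (Illumina TruSeq read-through stubs by
default), which is the geometry the merger must clip. Read length,
adapter and quality model are MiSeq-plausible defaults, fully
configurable; indels are not simulated (substitution-dominant Illumina
profile — a documented limitation, and consistent with the indel-free
primer matching below).

## Merging and barcode extraction

Merging scans **all** relative offsets (candidate insert lengths from
`min_overlap` to `len1+len2−min_overlap`), including the short-insert
regime, and keeps the offset maximising matching bases subject to overlap
≥ `min_overlap` (default 10) and mismatch fraction ≤ `max_mismatch_frac`
(default 0.10); ties prefer the larger overlap, then the smaller insert.
Consensus takes the higher-quality base at disagreements, ties to read 1.
Exhaustive scanning is exact and affordable at these insert sizes, and the
loop-based per-read implementation doubles as the oracle for the
vectorised batch engine (`delselect.bulk`), whose equivalence — statuses,
consensus, rejection reasons — is asserted by tests, not assumed. When no
offset passes the mismatch threshold the pair is classified
`too_many_mismatches` if some offset still matched at least
`min_overlap·(1−max_mismatch_frac)` bases, else `no_overlap`.

Extraction locates both primers by leftmost minimum-mismatch placement
(substitutions only; default tolerance 1 mismatch per primer, 0 in
exact-recovery tests) and accepts the enclosed region iff it has the
architecture's barcode length; failures carry a reason code
(`primer5_not_found`, `primer3_not_found`, `bad_barcode_length`) and are
logged, never silently dropped. Barcode counting is exact-match: the
experiment describes no error correction of the encoding region, so a
misread barcode becomes a (rare) novel singleton rather than being
collapsed onto a neighbour.

At error rate 0 with zero primer tolerance the recovered count table is
bit-identical to the simulated sequencing sample — the pipeline's
round-trip invariant.

## Enrichment analysis

Fold enrichment is the post/pre frequency ratio per barcode, computed over
the union of both tables with pseudocount smoothing
`(count+α)/(total+α·K)` (K = union size). Default α = 0.5
(Haldane–Anscombe) keeps barcodes unobserved in one sample finite and
flagged; α = 0 gives exact ratios and is used wherever results are
compared to closed forms. The 95% interval is a normal approximation on
the log ratio with variance `1/a − 1/n1 + 1/b − 1/n2` on smoothed counts.
Records sort by descending enrichment with the barcode as deterministic
tie-break; the spike's rank is computed among barcodes observed
pre-selection (barcodes absent pre have no defined frequency ratio).

Two spike enrichment figures are reported side by side, because the
experiment does not state which normalisation its printed value uses:
against the *measured* pre-selection frequency (`spike_enrichment`, the
primary figure) and against the nominal dilution
(`spike_enrichment_vs_nominal` = post-frequency × dilution). They agree
in expectation; the measured-pre version also cancels the small uniform
read-loss factor from sequencing errors.

The restriction-digest gel is emulated as `digest_fraction`: the
count-weighted fraction of molecules whose **assembled template** contains
the recognition site. Scanning the whole template (not just the barcode)
deliberately surfaces background barcodes that spuriously create the site
— with a 10⁵-member random background ~0.3% of pre-selection molecules
carry a spurious EcoRV site, which is exactly the kind of background a
real gel would show. Gel densitometry itself is not modelled; the digest
fraction is the same underlying frequency the gel band quantifies.

## Determinism and problem sizes

All randomness descends from a single run seed through spawned numpy
`SeedSequence` children (library, selection, pre-sample reads,
post-sample reads), so reruns are bit-identical, written artifacts
included. Full-scale runs use 10⁶ reads per sample over a 10⁵-member
background — the sequencing-scale study condition — and take well under a
minute each on one core thanks to the vectorised engine. The statistical
precision of a single simulated enrichment at 1/2000 dilution is limited
by the ~500 spike reads in the pre-selection sample (≈4.5% relative SE),
so headline reproductions average a handful of independent seeds.

## What the synthetic data does not emulate

- No indels, no quality-score variation along the read, no
  position-dependent or context-dependent error rates.
- No PCR amplification bias or duplicate structure; reads are exchangeable
  given the molecule counts.
- One Illumina sample per FASTQ pair; demultiplexing of barcoded adapters
  across samples is out of scope.
- The "catalyst" is an abstract class label — no chemistry, kinetics,
  DNA-templated proximity effects or inter-strand catalysis; all
  non-specific survival routes are folded into the single rate `p_bg`.

Consequently, passing tests demonstrate the correctness of the selection
arithmetic and of the read-processing chain under a clean substitution
error model; they do not certify performance on real MiSeq data with
indels, quality decay or amplification artifacts.
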