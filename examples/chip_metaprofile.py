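"""Simulate a repeat-family ChIP experiment and recover the injected promoters.

Builds a toy genome with 8 identical full-length elements and 6 solo LTRs,
simulates 30,000 IP fragments enriched at the element TSS (+238) and the
internal TSS (+1000) plus 30,000 uniform control fragments, runs the full
processing chain (dedup -> random multimapper assignment -> pileup ->
control normalization), and prints where the averaged metaprofile locates
the two promoter peaks and the promoter-balance ratio between them.
"""

import ty1kit as tk

model, _ = tk.build_toy_genome(n_full=8, n_solo=6, seed=1)
print(f"genome: {len(model.full_copies)} full copies + {len(model.solo_copies)} "
      f"solo LTRs on {sum(model.chrom_lengths.values()):,} bp")

spec = tk.EnrichmentSpec(
    components=(
        tk.EnrichmentComponent(center=238, weight=1.0, spread=50),
        tk.EnrichmentComponent(center=1000, weight=1.0, spread=50),
    ),
    background_weight=4.0,
)
ip = tk.simulate_fragments(model, spec, 30_000, seed=2)
control = tk.simulate_control(model, 30_000, seed=3)

ip_track, ip_assigned = tk.process_fragments(ip, model, seed=4)
ct_track, ct_assigned = tk.process_fragments(control, model, seed=5)
print(f"IP: {len(ip)} fragments, {len(ip_assigned)} after duplicate removal")
print(f"control: {len(control)} fragments, {len(ct_assigned)} after duplicate removal")

ratio = tk.normalize_to_control(ip_track, ct_track, pseudocount=0.5)
profile = tk.compute_metaprofile(ratio, model)

peaks = sorted(tk.profile_peaks(profile, n_peaks=2))
balance = tk.promoter_balance(profile, halfwidth=100)
print(f"recovered peaks at element coordinates {peaks} (injected at [238, 1000])")
print(f"promoter balance (internal TSS / element TSS) = {balance.ratio:.3f}")
print("a balance near 1 reflects the equal enrichment weights injected at the "
      "two promoters; shifting the weights shifts this ratio accordingly")
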