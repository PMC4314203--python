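# A small staggered community: three organisms at 8x / 2x / 0.4x.
# The most abundant organism is described by two references: a near-perfect
# one (97% of its sequence shared) and a distant relative (35% shared).
seed: 17
organisms:
  - {name: ecoli_like, genome_length: 200000, depth: 8.0}
  - {name: bacteroides_like, genome_length: 200000, depth: 2.0}
  - {name: rare_organism, genome_length: 200000, depth: 0.4}
references:
  - {ref_id: ecoli_ref, organism: ecoli_like, shared_fraction: 0.97, divergence: 0.01}
  - {ref_id: distant_ref, organism: ecoli_like, shared_fraction: 0.35, divergence: 0.02}
  - {ref_id: bacteroides_ref, organism: bacteroides_like, shared_fraction: 0.90, divergence: 0.01}
  - {ref_id: rare_ref, organism: rare_organism, shared_fraction: 0.98, divergence: 0.01}
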