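"""Call TF footprints from insertion coverage and show the binding dip.

Scans PWMs over the genome, scores every motif hit in every stage with
the purity statistic (1 - core/flank insertion rate), calls footprints
at purity >= 0.9, and aggregates the insertion profile around bound
sites — the dip-between-two-peaks signature of occupancy.
"""

from ocrdyn.core import GenomicInterval
from ocrdyn.footprints import MotifHit, aggregate_tag_density, call_footprints
from ocrdyn.simulate import SimulationConfig, run_simulation

config = SimulationConfig(seed=1, motif_fraction=0.25)  # TFs bound in N-d41 only
sim = run_simulation(config)

fps = call_footprints(sim.genome, sim.coverage, sim.pwms, purity_cutoff=0.9)
print("footprints called per (TF, stage):")
for (tf, stage), v in sorted(fps.items()):
    print(f"  {tf:>4} {stage:>6}: {len(v)}")

bound = sim.instances[sim.instances.bound]
called = sum(
    any(f.hit.interval.start < r.end and r.start < f.hit.interval.end
        and f.hit.interval.chrom == r.chrom for f in fps[(r.tf, "N-d41")])
    for r in bound.itertuples()
)
print(f"\nsensitivity at planted bound sites (N-d41): {called}/{len(bound)}")

hits = [MotifHit(r.tf, GenomicInterval(r.chrom, int(r.start), int(r.end), "+"), 0.0)
        for r in bound.itertuples()]
for stage in ("N-d41", "hiPSC"):
    prof = aggregate_tag_density(hits, sim.coverage[stage], stage)
    ratio = prof.central_mean(5) / prof.flank_mean(30)
    print(f"aggregate profile {stage:>6}: central/flank insertion ratio = {ratio:.2f}")
# A ratio well below 1 in N-d41 but near 1 in hiPSC shows the protected
# core appears only in the stage where the TF is actually bound.
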