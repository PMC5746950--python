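"""Build the coarse-grain molecule models and inspect their composition.

Tripalmitin maps 155 atoms onto 19 beads (16 apolar C1 + 3 ester Na);
Tween 20 maps 198 atoms onto 30 beads with a near-rigid 5-bead sorbitan
ring.  Every bead weighs 72 amu.
"""

from lnpsim import build_tripalmitin, build_tween20, default_forcefield
from lnpsim.topology import write_itp

tables = default_forcefield()

for build in (build_tripalmitin, build_tween20):
    topo = build(tables)
    counts = {t: topo.count_type(t) for t in ("C1", "Na", "P3") if topo.count_type(t)}
    n_ring = sum(b.is_ring for b in topo.beads)
    print(f"{topo.species_name}: {topo.n_beads} beads {counts}, "
          f"mass {topo.mass:.0f} amu, {len(topo.bonds)} bonds, "
          f"{len(topo.angles)} angles, {n_ring} ring beads")
    write_itp(topo, f"{topo.species_name}.itp")
    print(f"  wrote {topo.species_name}.itp (GROMACS-dialect topology)")

# The bead counts are the molecule's identity in this model: 19 beads
# (16 C1 + 3 Na) for the triglyceride, 30 beads for the surfactant.
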