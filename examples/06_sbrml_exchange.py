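"""Exchange a dataset with other tools via SBRML.

Writes an ensemble as an SBRML time-course document (one result component
per run), reads it back, and verifies the round trip is exact.
"""

from pathlib import Path

from trajstat import generate_ensemble, pure_death, read_sbrml, write_sbrml

ens = generate_ensemble(pure_death(mu=0.5, n0=10), n_runs=5, t_max=6.0, seed=6)
path = Path("example_output/dataset.sbrml.xml")
path.parent.mkdir(parents=True, exist_ok=True)
write_sbrml(ens, path)
back = read_sbrml(path)

print(f"wrote {ens.n_runs} result components to {path}")
print(f"round-trip identical: {back.equals(ens)}")
# Floats are serialised with 17 significant digits, so the document parses
# back to bit-identical trajectories — the file is a faithful interchange
# copy, not an approximation.
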