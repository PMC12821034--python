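# PyMOL example: overlay a solvent density map on a structure.
#
# Produce the inputs first, e.g.
#   hydrashell generate --out data --seed 1
#   hydrashell density --system-dir data/system --out shell.dx --ccp4
#
# Then from PyMOL:  @docs/visualize_density.pml

load data/system/frame0000.gro, frame
load shell.ccp4, shell_map

# first hydration layer: above-bulk electron density (bulk = 334 e/nm^3)
isosurface shell_hi, shell_map, 400
color orange, shell_hi
set transparency, 0.4, shell_hi

# depletion regions: below-bulk density
isosurface shell_lo, shell_map, 250
color skyblue, shell_lo
set transparency, 0.7, shell_lo

hide everything, frame and resn SOL
show spheres, frame and not resn SOL
color grey70, frame
bg_color white
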