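# Demo pipeline configuration (all keys optional; defaults are documented
# in mlklswitch.trajectory_io).  Residue intervals are 1-based, inclusive,
# in crystal-structure numbering.

# domain annotation
fourhb_range: [1, 130]
brace_range: [131, 178]
pseudokinase_range: [179, 464]
loop_helix_range: [343, 352]      # activation-loop helix (contains Q343/S345)
adjacent_helix_range: [228, 240]  # adjacent helix (contains T235)
hbond_donor: {residue: 219, atom: NZ}
hbond_acceptor: {residue: 343, atom: OE1}
chain_id: A

# pipeline parameters
frame_spacing_ps: 10.0
bin_width: 2.0                    # degrees, pooled angle histograms
hbond_max_heavy_distance: 3.5     # Angstrom
hbond_min_dha_angle: 135.0        # degrees, only used with explicit hydrogens
n_permutations: 1000000
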