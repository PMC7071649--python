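# bHLH domain site configuration (consensus-column coordinates, 1..55).
# Region boundaries partition the 55 consensus columns.
basic_region = 1-15
helix1 = 16-28
loop = 29-42
helix2 = 43-55
# Residues counted as basic in the basic region.
basic_residues = RKH
# DNA-binding recognition sites: column:allowed-residues, comma separated.
# E-box sites must all be present for E-box capacity; the G-box sites extend
# them for G-box capacity.
ebox_sites = 13:E,16:R,17:R
gbox_sites = 9:HK,13:E,17:R
# Profile scan parameters (bits). min_score was calibrated once as the mean
# planted-domain score minus 3 standard deviations within the lowest-scoring
# binding category (atypical domains) of the synthetic calibration set
# (seed 20200314, n=200); random background sequences score below 0 bits.
gap_open = 10.0
gap_extend = 2.0
min_score = 52.9
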