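>cox2_reference_synthetic constructed COX2-like reference protein (synthetic stand-in; replaceable)
MSYNQLGFQDAASPVLLVIALLVAFILLFVAGLIVIALMLNKYSEFVIITAIVLILIALGFLVFMALSFA
QEVDSPHNTMHQWYWSYEYSDFNNVEFDSYMTPTSELNEGQFRLLETDNRVVLPMNTQVRMLVTAADVIH
SWTVPSLGVKVDATPGRLNQGQCSELCGMNHSFMPIVVEAVSLDKFVNWISSRMEPGVFYGQCSEICGSN
HAFMPIVVEAVPLNHFENWSASML
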