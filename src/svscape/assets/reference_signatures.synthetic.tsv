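# Synthetic stand-in reference SV-signature catalog (32 channels).
# Profiles are constructed to echo the qualitative character of the
# ten published rearrangement signatures (SV1-SV10) and are NOT the
# published values; replace with a licensed catalog for real analyses.
	clustered_del_1-10Kb	clustered_del_10-100Kb	clustered_del_100Kb-1Mb	clustered_del_1Mb-10Mb	clustered_del_>10Mb	clustered_dup_1-10Kb	clustered_dup_10-100Kb	clustered_dup_100Kb-1Mb	clustered_dup_1Mb-10Mb	clustered_dup_>10Mb	clustered_inv_1-10Kb	clustered_inv_10-100Kb	clustered_inv_100Kb-1Mb	clustered_inv_1Mb-10Mb	clustered_inv_>10Mb	clustered_trans	non-clustered_del_1-10Kb	non-clustered_del_10-100Kb	non-clustered_del_100Kb-1Mb	non-clustered_del_1Mb-10Mb	non-clustered_del_>10Mb	non-clustered_dup_1-10Kb	non-clustered_dup_10-100Kb	non-clustered_dup_100Kb-1Mb	non-clustered_dup_1Mb-10Mb	non-clustered_dup_>10Mb	non-clustered_inv_1-10Kb	non-clustered_inv_10-100Kb	non-clustered_inv_100Kb-1Mb	non-clustered_inv_1Mb-10Mb	non-clustered_inv_>10Mb	non-clustered_trans
SV1	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.354709	0.40481	0.124248	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008
SV2	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.879377
SV3	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.204409	0.45491	0.224449	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008	0.004008
SV4	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.876984	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968	0.003968
SV5	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.003929	0.220039	0.298625	0.249509	0.121807	0.003929	0.003929
SV6	0.004175	0.004175	0.004175	0.004175	0.296451	0.004175	0.004175	0.004175	0.004175	0.265136	0.004175	0.004175	0.004175	0.004175	0.317328	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175
SV7	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.473904	0.400835	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175	0.004175
SV8	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.866379	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431	0.00431
SV9	0.004219	0.004219	0.004219	0.267932	0.004219	0.004219	0.004219	0.004219	0.267932	0.004219	0.004219	0.004219	0.004219	0.341772	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219	0.004219
SV10	0.29572	0.29572	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.178988	0.120623	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891	0.003891
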