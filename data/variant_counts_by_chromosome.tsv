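chrom	raw_snp	raw_indel	filtered_snp	filtered_indel
Chr01	809046	139387	519110	133213
Chr02	685281	138448	464550	133805
Chr03	918813	165558	581996	160415
Chr04	858671	147249	564337	141912
Chr05	560582	110072	361072	105493
Chr06	925223	171679	579010	166158
Chr07	712969	143049	463300	138337
Chr08	693324	147969	456798	143504
Chr09	743949	141684	481385	136143
Chr10	714099	134919	462054	129213
Chr11	438702	95978	303411	92734
Chr12	595004	115856	391525	111748
Chr13	722750	160407	481921	156154
Chr14	902138	151259	590557	145723
Chr15	1048862	175748	648774	170120
Chr16	861304	165506	526504	160445
Chr17	642407	125991	425846	122022
Chr18	1272177	224567	794961	217759
Chr19	804396	144788	512977	139773
Chr20	767005	136478	506619	131009
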