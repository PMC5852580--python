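gene_id	chromosome	start	end	strand
CmaGSTU1	13	8381645	8382352	+
CmaGSTU2	11	1483599	1484338	+
CmaGSTU3	14	13801828	13805918	+
CmaGSTU4	06	7777316	7778827	-
CmaGSTU5	00	47643604	47645087	-
CmaGSTU6	06	8499592	8500393	-
CmaGSTU7	14	13214607	13217686	-
CmaGSTU8	06	8501349	8502406	+
CmaGSTU9	14	13213235	13214322	-
CmaGSTU10	03	4366133	4366923	+
CmaGSTU11	07	5378533	5380070	-
CmaGSTU12	16	2333498	2334374	+
CmaGSTU13	04	3269916	3271375	-
CmaGSTU14	16	2326120	2328293	+
CmaGSTU15	04	3271577	3272321	-
CmaGSTU16	04	3273122	3286431	-
CmaGSTU17	04	15857294	15858045	-
CmaGSTU18	04	3268691	3269778	-
CmaGSTF1	08	2344840	2346569	+
CmaGSTF2	08	2346863	2348162	-
CmaGSTF3	12	1988809	1990016	-
CmaEF1G1	16	4206363	4213994	+
CmaEF1G2	04	4645271	4652681	+
CmaEF1G3	06	5603706	5606718	-
CmaGSTT1	16	3054792	3058033	-
CmaGSTT2	00	47643604	47645087	+
CmaGSTZ1	02	3895323	3899120	+
CmaGSTZ2	02	3887013	3892301	+
CmaGSTZ3	06	7652425	7656514	+
CmaGSTL1	06	1588222	1591488	-
CmaGHR1	18	3671672	3674403	-
CmaGHR2	19	681203	684746	+
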