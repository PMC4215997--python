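gene_id	position	wild	cultivar
Gmcupin03.1	39840871	11C/5T	5C/9T
Gmcupin03.1	39841560	8G/7T	0G/13T
Gmcupin03.1	39841777	8C/3T	3C/8T
Gmcupin03.1	39842153	10T/6A	6T/8A
Gmcupin03.1	39842186	9T/5C	4T/7C
Gmcupin03.1	39842508	10A/5G	5A/9G
Gmcupin03.1	39842704	10T/6A	5T/8A
Gmcupin07.1	3163748	12A/4C	4A/9C
Gmcupin07.1	3164179	10A/5T	4A/9T
Gmcupin07.2	3167526	13T/4C	4T/10C
Gmcupin07.2	3167819	12T/4C	4T/10C
Gmcupin07.2	3167944	14G/3T	4G/10T
Gmcupin07.2	3168029	13T/2C	4T/8C
Gmcupin07.2	3168069	13T/2A	4T/8A
Gmcupin07.4	3179898	14T/2C	4T/10C
Gmcupin10.1	7200497	9C/6A	2C/12A
Gmcupin10.1	7200888	13A/4G	2A/12G
Gmcupin10.1	7200956	8G/8A	2G/12A
Gmcupin10.1	7201734	12T/4C	2T/12C
Gmcupin10.3	36808227	9T/7A	1T/13A
Gmcupin10.3	36808469	10G/5A	1G/13A
Gmcupin10.3	36808488	10A/5G	1A/13G
Gmcupin10.3	36808586	10A/4T	1A/13T
Gmcupin10.4	36812510	9C/6T	1C/13T
Gmcupin10.4	36812530	10G/6A	1G/13A
Gmcupin10.4	36812729	8G/6C	1G/13C
Gmcupin10.7	39767387	14T/1C	4T/5C
Gmcupin10.7	39768245	11T/1A	4T/6A
Gmcupin13.1	20816255	13C/4A	5C/8A
Gmcupin13.2	22112820	9C/7G	5C/9G
Gmcupin16.4	5853162	12C/4G	6C/8G
Gmcupin16.4	5853378	11A/6G	6A/7G
Gmcupin16.4	5853406	11G/5T	6G/8T
Gmcupin16.8	5951996	10T/4C	3T/7C
Gmcupin17.1	4052528	10A/5C	4A/9C
Gmcupin19.13	42367147	10C/4T	6C/8T
Gmcupin19.15	47524873	8A/8G	5A/9G
Gmcupin20.1	32106107	9G/8T	1G/12T
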