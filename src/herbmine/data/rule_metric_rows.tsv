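ranking	antecedents	consequents	antecedent_support	consequent_support	support	confidence	lift	leverage	conviction
support	蜜	甘草	0.939	0.947	0.930	0.990	1.045	0.040	5.167
support	甘草	蜜	0.947	0.939	0.930	0.982	1.045	0.040	3.381
support	清	甘草	0.978	0.947	0.927	0.948	1.001	0.001	1.025
support	甘草	清	0.947	0.978	0.927	0.980	1.001	0.001	1.065
support	清	蜜	0.978	0.939	0.920	0.941	1.001	0.001	1.019
support	蜜	清	0.939	0.978	0.920	0.979	1.001	0.001	1.057
support	清	木	0.978	0.932	0.915	0.936	1.004	0.003	1.053
support	木	清	0.932	0.978	0.915	0.982	1.004	0.003	1.199
support	甘草	蜜,清	0.947	0.920	0.910	0.962	1.045	0.039	2.083
support	醋	蜜	0.927	0.939	0.910	0.982	1.045	0.039	3.312
support	當歸	甘草	0.918	0.947	0.910	0.992	1.048	0.042	6.730
support	醋	甘草	0.927	0.947	0.910	0.982	1.037	0.032	2.915
support	甘草	當歸	0.947	0.918	0.910	0.962	1.048	0.042	2.146
support	蜜	醋	0.939	0.927	0.910	0.969	1.045	0.039	2.349
support	蜜	清,甘草	0.939	0.927	0.910	0.969	1.045	0.039	2.349
support	清,甘草	蜜	0.927	0.939	0.910	0.982	1.045	0.039	3.312
support	蜜,清	甘草	0.920	0.947	0.910	0.989	1.045	0.039	5.061
support	清	蜜,甘草	0.978	0.930	0.910	0.931	1.001	0.001	1.013
support	蜜,甘草	清	0.930	0.978	0.910	0.979	1.001	0.001	1.046
support	甘草	醋	0.947	0.927	0.910	0.962	1.037	0.032	1.893
lift	當歸,醋,甘草	枳殻,蜜	0.886	0.821	0.804	0.907	1.105	0.076	1.929
lift	枳殻,蜜	當歸,醋,甘草	0.821	0.886	0.804	0.979	1.105	0.076	5.511
lift	當歸,蜜,醋,甘草	枳殻	0.884	0.823	0.804	0.910	1.105	0.076	1.955
lift	枳殻	當歸,蜜,醋,甘草	0.823	0.884	0.804	0.976	1.105	0.076	4.939
lift	大黄	黄芩	0.852	0.852	0.801	0.940	1.103	0.075	2.476
lift	黄芩	大黄	0.852	0.852	0.801	0.940	1.103	0.075	2.476
lift	當歸,醋	枳殻,蜜	0.891	0.821	0.806	0.905	1.102	0.075	1.884
lift	枳殻,蜜	當歸,醋	0.821	0.891	0.806	0.982	1.102	0.075	6.156
lift	枳殻,蜜,甘草	當歸,醋	0.818	0.891	0.804	0.982	1.102	0.075	6.138
lift	當歸,醋	枳殻,蜜,甘草	0.891	0.818	0.804	0.902	1.102	0.075	1.856
lift	枳殻	當歸,蜜,醋	0.823	0.889	0.806	0.979	1.102	0.075	5.410
lift	當歸,蜜,醋	枳殻	0.889	0.823	0.806	0.907	1.102	0.075	1.908
lift	枳殻,甘草	當歸,蜜,醋	0.821	0.889	0.804	0.979	1.102	0.074	5.394
lift	當歸,蜜,醋	枳殻,甘草	0.889	0.821	0.804	0.905	1.102	0.074	1.879
lift	當歸,醋,甘草	枳殻	0.886	0.823	0.804	0.907	1.102	0.074	1.903
lift	枳殻	當歸,醋,甘草	0.823	0.886	0.804	0.976	1.102	0.074	4.837
lift	木香,當歸	白术,蜜,醋	0.872	0.835	0.801	0.919	1.101	0.073	2.044
lift	白术,蜜,醋	木香,當歸	0.835	0.872	0.801	0.959	1.101	0.073	3.162
lift	白术,醋	木香,當歸,蜜	0.840	0.867	0.801	0.954	1.100	0.073	2.888
lift	木香,當歸,蜜	白术,醋	0.867	0.840	0.801	0.925	1.100	0.073	2.119
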