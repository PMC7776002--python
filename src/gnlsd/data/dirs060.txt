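0.06839063212546424 -0.2180738654392156 -0.9735330043968093
0.3184752959040899 0.03948805724471697 -0.9471083249733582
0.2128892171280058 0.3561179825619694 -0.9098671132240232
0.4065548518867911 -0.2790974344894811 -0.869952742664048
0.1543458381159464 -0.5106473040460855 -0.8458230861869112
0.5227043067113061 0.3021838820539383 -0.7971606545560714
0.6224284604022922 -0.0272982917570776 -0.7822004953644415
0.01005063276654326 0.6413537484822903 -0.7671794797103917
0.345581650193825 0.6063578796686561 -0.7161727758111477
0.4328781980809797 -0.5838456380182541 -0.6868338493356465
0.6795985979968192 -0.3312192173997793 -0.6545529586105585
0.7773736424982152 0.1992236792370376 -0.5966574776036205
0.1881715786002962 -0.7898447999331614 -0.58372651903577
0.6214676133911725 0.5444323452110865 -0.5633572818326187
0.1626743310734854 0.8281692244935827 -0.5363513751371317
0.8635837937153872 -0.1173260834094249 -0.4903647839965103
0.6598757777251335 -0.5984094445614934 -0.4543898047175524
0.4616850936800696 0.7941149704632442 -0.3952572427670191
0.4379582847491431 -0.8217875556021873 -0.3644965764955422
0.8316895672708082 0.4255549004718361 -0.3566447677694168
0.8623526084805587 -0.4036715582338831 -0.3056096394418948
0.1332391705517768 -0.9486780533676085 -0.286805290204556
0.9499864512500263 0.1288708290370448 -0.2844609847847085
0.2255245003819893 0.9533206437811818 -0.2007945464102229
0.698557213558115 0.6877845070121885 -0.1974089443260438
0.6973883518482094 -0.7030694572923042 -0.13907848478159
0.978413511860576 -0.1671557873386506 -0.1215151948023379
0.4321646428515272 -0.9008297876053754 -0.04170629726871114
0.896889367058181 0.4405866073778912 -0.03837844000497369
0.4877685519516965 0.8728430980408864 -0.01505874926189669
0.1122603721239014 -0.9932011270626647 0.03080795436336665
0.8787446493447851 -0.4758278989971799 0.03735842319798591
0.9904945128049409 0.1292909402110271 0.04695181447666814
0.1948404092017202 0.9711584924130525 0.1374350666901041
0.7163578961097326 0.680587078810285 0.1537289590081213
0.6780350974041481 -0.7096260407092543 0.1915705849953355
0.9539378792275425 -0.2054674028190264 0.2185993342937313
0.3998900148236615 -0.8721489403605971 0.281858478446577
0.8687027102478575 0.4035230454031427 0.2872712186011687
0.4642541161894369 0.820923325036478 0.332495127802225
0.07723105731218595 -0.936644743766247 0.3416606324432236
0.9267859646923335 0.08949293525032689 0.364772244269738
0.8023456386691473 -0.4490089045103276 0.393233365546508
0.1566946720211774 0.8763471720340933 0.4554804209052492
0.6635778135676527 0.5656456549225646 0.4896013464115436
0.5586390500267093 -0.655196261565793 0.5085668791963005
0.8159278036993169 -0.1362411445812158 0.5618720225047777
0.2326402241695336 -0.7801764019259535 0.5806920939501605
0.7593709704794019 0.2512611923189847 0.6001862564467914
0.3991449887289078 0.6559067359653713 0.6406790395259179
0.6270309917887732 -0.3551926901880197 0.6933038930897365
0.09118696083525216 0.6886915682950434 0.7192974780526785
0.3600524280783314 -0.5374674879064947 0.7625555379632227
0.5088274978161359 0.3627905061993593 0.7806904803299339
0.6127420938285993 0.01933082329082027 0.7900464832662968
0.1974115239013903 0.4222843589670194 0.8847059457258918
0.3933973655601102 -0.2001538215864637 0.8973165330443318
0.1164377074746286 -0.3804445286948513 0.9174443966062495
0.30441555236416 0.1178495784238652 0.9452209521292577
0.03106248223788175 -0.08275282052806564 0.9960858863029185
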