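0.06360893831029407 -0.1911509833221129 -0.9794974244693176
0.2144386142838243 0.064657640998213 -0.9745950288014911
0.1694785989132659 0.3163869659516432 -0.9333682511668746
0.3455315228652673 -0.1478877580457736 -0.9266807312805225
0.1899041772624505 -0.41245965542743 -0.8909620845484715
0.4430515623860328 0.1582795090592094 -0.8824131175811423
0.06174443177996528 0.561113968162436 -0.8254324562780251
0.4601704475262403 -0.3448526447279296 -0.8181196811271881
0.3269754316777947 0.4842121834065109 -0.811557532476792
0.5880449940662141 -0.07104301687280891 -0.8057021625310907
0.03892467499317141 -0.6405658833721402 -0.7669160441250042
0.5482895160695452 0.3583128211488747 -0.7556391524852049
0.3089707256228273 -0.6010870008608922 -0.7370424059063098
0.7025013846574132 0.1525044506219267 -0.6951504852151954
0.7009126470733482 -0.2773190699877859 -0.6571267720871991
0.2566648687846606 0.7090437719645576 -0.6567953064464037
0.5591312958794314 -0.5143856736180117 -0.6502150203930481
0.514388875023604 0.5943748036314038 -0.6181607218677692
0.8143978958072292 -0.05154288972211418 -0.5780133197633525
0.1988195473763106 -0.7956271119837126 -0.5722309728226321
0.7311606781325327 0.4055535449776522 -0.5485712213640398
0.4692327541032891 -0.7166992427300586 -0.5159096994114403
0.7321914112998238 -0.5057478786715507 -0.456196032904714
0.1788983654471896 0.8755093447294852 -0.4488638570119801
0.8704461918376687 0.2052934450750207 -0.4474125931671235
0.4457450503200285 0.7806006101681446 -0.4381484195113745
0.8668875916049705 -0.2821209637165764 -0.4109910769748706
0.6829367997835077 0.6184492262467003 -0.3887388352818881
0.09181170116981766 -0.9287772573967096 -0.3590869221664167
0.3716620182262285 -0.8666662659848713 -0.3328016340282105
0.9426521208795533 -0.03110576402145279 -0.3323242549768549
0.6436357849974247 -0.704707575483564 -0.2985300811087986
0.8532380096040988 0.4435887651399704 -0.2742515385707652
0.3610477280289075 0.9066163776617941 -0.2183833369114301
0.8362873683183967 -0.5099052139314996 -0.2015443137291698
0.1092594818762483 0.9759737193500401 -0.1885143622066575
0.6167273434705401 0.764525593375126 -0.1874780010832786
0.9595003358224048 0.2226987668688458 -0.1725235195322306
0.9508707374114711 -0.2747931866194144 -0.1425957408975213
0.2578041226725515 -0.9591849264746294 -0.1161951425701439
0.5401947714605414 -0.8355653323602285 -0.1001008703480357
0.9972825931796034 -0.02293830991108402 -0.07000902284269335
0.7944505681034331 0.6040096107628184 -0.06340887119544977
0.7446174604541008 -0.6674567251512159 -0.006808644307036002
0.4934320298205292 0.8695512017127798 0.02013801249014075
0.9206875363072745 0.3884580934768834 0.03787835926681696
0.2549436078259377 0.9646903091450735 0.0661540948866893
0.8975102025205826 -0.4339206365368824 0.07866586018655072
0.002217481916621064 0.9953869393473082 0.09591623298872681
0.400134780111576 -0.9097437718592687 0.1107177822589101
0.981439993548789 0.1327362524450166 0.1384074649352613
0.6698598583797959 0.7276442735288229 0.1477212961360388
0.9729597006453056 -0.1746227838970704 0.1511830157928945
0.1472232488452082 -0.9761312211570143 0.1596657573870433
0.6043546119043759 -0.7697477473425869 0.2055332297486812
0.8083459583031594 0.5336072403994895 0.2486767473813915
0.7736657574739634 -0.5716854657350828 0.2731611685058838
0.436636679918637 0.8520192062934842 0.2888108063363473
0.8981857274719443 0.2943469155968038 0.3265306911215885
0.1782941168431999 0.9240227878842849 0.3382204833679611
0.8791583534371429 -0.3147300202657538 0.3578066571840301
0.3553120145271924 -0.8594181902736612 0.367632624449155
0.9273798311352781 -0.01279033823600533 0.3739024686349523
0.08882588970640344 -0.9028149732386516 0.4207553747891508
0.6064473487091718 0.6744761343973463 0.4210742896117369
0.5561461967586597 -0.6898056355103466 0.4635402820133813
0.7335383447872283 0.4474097504905926 0.5116111921105314
0.7166309464771002 -0.4689968210927655 0.5162190120057726
0.3509598823696622 0.76934017070873 0.533800395935536
0.8188574618449314 0.1727026574594217 0.5473995335103333
0.8058087592494959 -0.1581039012323212 0.5706797700391246
0.07929966969875536 0.813379766155461 0.5763028009601859
0.2888670194037315 -0.747406993334401 0.5982797267295916
0.01582304357127445 -0.7619459305024804 0.6474473185386213
0.5032911759094958 0.5628156715897971 0.6556954415462735
0.4758325723358492 -0.5523284168258127 0.6844827850800488
0.6313383553692666 -0.3179184665913956 0.7073469655266823
0.6181379723643194 0.3142162995281219 0.7205369971293504
0.6908569375360304 0.03572675662893968 0.722108226458551
0.2356272736786885 0.6276878151949923 0.7419486468445682
0.2052890976837412 -0.575196259729587 0.7918368829280996
0.3645085379359039 0.4005409565821124 0.8406547851955142
0.526215507293476 -0.1254218540356512 0.8410508893129651
0.370447462444447 -0.3603357112383191 0.8561114721663557
0.462199937911981 0.1439923393151642 0.8750070991784624
0.09166430547298948 0.4291967838632333 0.898547592408778
0.1052179126823793 -0.3428048514198108 0.9334955943622897
0.2914066800890214 -0.09737449966818146 0.9516303660633504
0.2071154107180268 0.1789067810793299 0.96181888644741
0.04236243200429138 -0.07573623670828179 0.9962276079310133
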