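"gene","logFC","AveExpr","t","P","s2_post","d0","s2_prior"
"g000",1.27989940303958,7.49378872744538,3.97022037489418,0.00121995581134334,0.311776731716687,5.08092003324332,0.178097546715981
"g001",2.25029611027278,5.44952152513807,7.71264662910474,1.3014455999329e-06,0.255384024320741,5.08092003324332,0.178097546715981
"g002",1.6539492256395,7.6330153798496,6.21147955874896,1.62560090686939e-05,0.212703913349134,5.08092003324332,0.178097546715981
"g003",1.325297109435,6.97238753481334,3.40547179067363,0.00388774944555164,0.454352771895989,5.08092003324332,0.178097546715981
"g004",1.31052672597661,3.30845965320332,4.81791003281172,0.00022250590463102,0.221970697627203,5.08092003324332,0.178097546715981
"g005",-0.104823060103313,8.01311144585054,-0.355153513939647,0.727392766299446,0.261338076672475,5.08092003324332,0.178097546715981
"g006",0.107513869459795,6.67598895676065,0.381351784073733,0.708261316348755,0.238450740159186,5.08092003324332,0.178097546715981
"g007",0.0860400318096386,6.54104640684193,0.403711846492639,0.692091122019442,0.136263453700295,5.08092003324332,0.178097546715981
"g008",-0.0826844777939579,2.78925071740146,-0.525142811698535,0.607118821899713,0.0743728424844367,5.08092003324332,0.178097546715981
"g009",-0.259604853332303,4.66488409000656,-0.779205774325068,0.447914176250451,0.332998705320265,5.08092003324332,0.178097546715981
"g010",0.498780929182406,4.15705732168224,1.89613207638173,0.0772683519291797,0.207588726351956,5.08092003324332,0.178097546715981
"g011",-0.237535072279198,7.53434793389209,-1.08638672490697,0.29436804521263,0.143419379720366,5.08092003324332,0.178097546715981
"g012",-0.00287487700566583,6.05973446924663,-0.00982325578316786,0.992291073379818,0.256950157375598,5.08092003324332,0.178097546715981
"g013",-0.170304615355203,6.93864265606322,-0.776464339523411,0.449482260061908,0.144321508841559,5.08092003324332,0.178097546715981
"g014",-0.041221051387035,4.6328686770993,-0.23388519652171,0.818219400267927,0.0931866962813978,5.08092003324332,0.178097546715981
"g015",0.17619437663075,3.40850332741774,0.694158270140816,0.498137494664176,0.193280632137024,5.08092003324332,0.178097546715981
"g016",-0.285799879037064,5.45612109282304,-1.45398783889508,0.166443971995081,0.115910769173147,5.08092003324332,0.178097546715981
"g017",-0.406929406558069,2.46154673235763,-1.18171097130468,0.255619800909844,0.355743414798753,5.08092003324332,0.178097546715981
"g018",-0.19313738329271,6.88891007705242,-0.563056680897897,0.581671477115772,0.352979683275568,5.08092003324332,0.178097546715981
"g019",0.104999162324139,5.96639791899161,0.339123064445908,0.73919314177278,0.287592970965763,5.08092003324332,0.178097546715981
"g020",0.167207022877202,6.54845586724208,0.608242519063966,0.552077869082796,0.226713160415311,5.08092003324332,0.178097546715981
"g021",-0.411688923444097,4.35928268279691,-1.54869501271859,0.142181939593769,0.211996074836357,5.08092003324332,0.178097546715981
"g022",0.101066340667226,7.38302327858691,0.278651579092562,0.784296810109735,0.394649285144393,5.08092003324332,0.178097546715981
"g023",-0.047811792639989,7.41761806243535,-0.301031526394498,0.767501093185435,0.0756775995224431,5.08092003324332,0.178097546715981
"g024",0.313118309446636,6.59922758582347,1.79567085338005,0.0926070057790603,0.0912188756625766,5.08092003324332,0.178097546715981
"g025",0.0772505872586844,3.14143633035077,0.406691500000487,0.689947738828092,0.108241709540311,5.08092003324332,0.178097546715981
"g026",0.0542536542305874,4.59472085270971,0.191417773943315,0.850751642356792,0.240998712483067,5.08092003324332,0.178097546715981
"g027",0.40913004778457,2.51499479051013,1.57046087826034,0.137048548834859,0.203605621040657,5.08092003324332,0.178097546715981
"g028",-0.322751069193868,2.80231535547676,-1.84372788114407,0.0849608055706319,0.0919312123848427,5.08092003324332,0.178097546715981
"g029",-0.135651882427792,6.1746960455985,-0.516858029670196,0.612751745342914,0.206647601539196,5.08092003324332,0.178097546715981
"g030",-0.27657158296402,6.56983682114457,-1.51764666300742,0.149785209182325,0.099631122392287,5.08092003324332,0.178097546715981
"g031",-0.580750267447383,7.74598563033359,-1.66005970782377,0.117547086936523,0.367157728423718,5.08092003324332,0.178097546715981
"g032",0.0729065813865507,3.76732487948791,0.218107551512969,0.830269135558055,0.335207185034292,5.08092003324332,0.178097546715981
"g033",-0.242471695474946,4.36170156580268,-1.03388850602267,0.317483944831578,0.165004557140408,5.08092003324332,0.178097546715981
"g034",-0.153763544884649,4.87418872184243,-0.678425202641518,0.507779519090035,0.154107606061749,5.08092003324332,0.178097546715981
"g035",0.556670300852266,2.87312121126954,2.10248814456787,0.052711720033833,0.210305314166945,5.08092003324332,0.178097546715981
"g036",-0.454231292564236,2.75253792927356,-2.26371879157361,0.0387632037033558,0.120789839078212,5.08092003324332,0.178097546715981
"g037",-0.0644106290702836,4.82676617988055,-0.387826283289851,0.703563775086492,0.0827488295885967,5.08092003324332,0.178097546715981
"g038",-0.164765113728258,3.34361929052781,-0.750336265506178,0.464598742679639,0.144657150104748,5.08092003324332,0.178097546715981
"g039",-0.0132465137779369,5.86449405006766,-0.0285609026383449,0.977589327916747,0.645328117768123,5.08092003324332,0.178097546715981
"g040",0.11382768455379,4.5620209748858,0.29763794647654,0.770040418585041,0.438773569535456,5.08092003324332,0.178097546715981
"g041",0.54232555765441,6.86789179694696,2.02595213651564,0.0608386610412971,0.214972563815578,5.08092003324332,0.178097546715981
"g042",-0.130215535600454,6.16871613323211,-0.449224468767177,0.659658187997914,0.252069355162194,5.08092003324332,0.178097546715981
"g043",0.227425794456901,3.88423944716759,0.607266255129909,0.552708562941609,0.420767704107166,5.08092003324332,0.178097546715981
"g044",0.0497091663749325,7.05535284800705,0.133237432725397,0.895767243994877,0.417581935556097,5.08092003324332,0.178097546715981
"g045",-0.414075004779077,6.40461842308757,-1.20160124749138,0.248048727492196,0.356253011901464,5.08092003324332,0.178097546715981
"g046",0.33293958936224,4.50790715721222,1.39915403383943,0.181997475395401,0.169871716811878,5.08092003324332,0.178097546715981
"g047",-0.255558040322352,3.72966721299872,-1.14656205171462,0.269429426320316,0.149040818126106,5.08092003324332,0.178097546715981
"g048",0.251935682801579,5.96270335233194,1.45182480422495,0.167036007738553,0.0903383588644693,5.08092003324332,0.178097546715981
"g049",-0.508391301392737,2.67849007698386,-1.70816728038939,0.108100587454508,0.265739846270125,5.08092003324332,0.178097546715981
"g050",0.272027324612059,3.01044682981287,0.930892862798588,0.366572184384746,0.256180998542407,5.08092003324332,0.178097546715981
"g051",-0.0748000303693761,2.07659731200935,-0.346046929266978,0.734087814188695,0.140169912925245,5.08092003324332,0.178097546715981
"g052",-0.0627961548344168,6.71976692066241,-0.239173158849521,0.81419126877228,0.206805687799366,5.08092003324332,0.178097546715981
"g053",-0.193317108390991,6.25176958761551,-0.664821740001638,0.51620277360048,0.253659662463598,5.08092003324332,0.178097546715981
"g054",-0.0965840935751674,6.33663090362831,-0.465016626402089,0.648563061386552,0.129418245914327,5.08092003324332,0.178097546715981
"g055",-0.291600181595672,6.69547840236182,-0.952872059552995,0.355678914792243,0.280949102928808,5.08092003324332,0.178097546715981
"g056",0.457950440549417,4.65455157727639,1.40709545234491,0.179673764258391,0.317768686021027,5.08092003324332,0.178097546715981
"g057",-0.301909007217081,5.44412768391007,-1.2073980682864,0.245875043389918,0.18757391432374,5.08092003324332,0.178097546715981
"g058",-0.215406820629117,2.62845584244317,-0.820180219134684,0.424887642269784,0.206929102561507,5.08092003324332,0.178097546715981
"g059",-0.236859378908248,2.6083324653967,-0.648848093887788,0.526194796374567,0.399775670824482,5.08092003324332,0.178097546715981
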